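"""Crossover detection probabilities under equational segregation.

After meiotic prophase-I recombination, an RTG cell segregates its four
chromatids equationally: the mother receives one chromatid of each original
sister pair, the daughter the other two.  A crossover is observable only
when it changes the zygosity across its breakpoint in the resulting
diploids; with a single CO per arm this happens in half of the
segregations, and the detection rate climbs toward 2/3 as more COs
accumulate on one arm.

The generative model enumerated here: two homologs, each replicated into two
sister chromatids joined at the centromere, giving four chromatids whose
distal content starts as (P1, P1, P2, P2).  COs are applied proximal to
distal; each uniformly picks one of the four chromatid pairs of *opposite
current distal content* and exchanges distal content.  Segregation then
uniformly sends one chromatid of each original sister pair to the mother.
Detected COs per outcome are counted as one per terminal rLOH tract and two
per interstitial tract — equivalently, one per zygosity change along the
arm.  An alternative "inter-homolog" rule (uniform over the four
homolog-crossing pairs, content-neutral exchanges allowed) is provided for
model comparison; it does not reproduce the observed detection rates
(it yields 37.5% at k=2 instead of 62.5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

OPPOSITE_CONTENT = "opposite_content"
INTER_HOMOLOG = "inter_homolog"

_INITIAL = (0, 0, 1, 1)  # distal parental content; sisters (0,1) and (2,3)
_SEGREGATIONS = ((0, 2), (0, 3), (1, 2), (1, 3))
_INTER_HOMOLOG_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))
_MAX_EXHAUSTIVE_K = 8


def _choice_pairs(content: tuple[int, ...], rule: str) -> tuple[tuple[int, int], ...]:
    if rule == INTER_HOMOLOG:
        return _INTER_HOMOLOG_PAIRS
    return tuple(
        (a, b) for a in range(4) for b in range(a + 1, 4) if content[a] != content[b]
    )


@dataclass(frozen=True)
class DetectionResult:
    """Exact detection statistics for ``k`` COs on one chromosome arm."""

    k: int
    rule: str
    p_detect: Fraction  # E[detected COs] / k
    e_detected: Fraction
    e_terminal: Fraction  # expected number of terminal rLOH tracts
    e_interstitial: Fraction
    var_detected: Fraction
    #: distribution over (detected, n_terminal, n_interstitial) outcomes
    outcomes: tuple[tuple[tuple[int, int, int], Fraction], ...] = ()

    @property
    def percent(self) -> float:
        """Detection probability as the conventionally printed percentage."""
        return round(100 * float(self.p_detect), 1)


def enumerate_detection(k: int, rule: str = OPPOSITE_CONTENT) -> DetectionResult:
    """Exhaustively enumerate the detection outcome distribution for ``k`` COs.

    Walks every sequence of pair choices (4^k paths, equally likely under
    either rule) times the four equational segregations, tracking per
    segregation the zygosity of the current distal interval and the number
    of zygosity changes so far.  All results are exact rationals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > _MAX_EXHAUSTIVE_K:
        raise ValueError(
            f"exhaustive enumeration limited to k <= {_MAX_EXHAUSTIVE_K}; "
            "use detection_table() for larger k"
        )
    tallies: dict[tuple[int, int, int], int] = {}
    # state: content tuple, per-segregation (zygosity_is_hom, transitions)
    init_z = tuple(_INITIAL[a] == _INITIAL[b] for a, b in _SEGREGATIONS)
    stack = [(_INITIAL, init_z, (0, 0, 0, 0), 0)]
    while stack:
        content, zyg, trans, depth = stack.pop()
        if depth == k:
            for z, t in zip(zyg, trans):
                term = 1 if z else 0
                inter = (t - term) // 2
                key = (t, term, inter)
                tallies[key] = tallies.get(key, 0) + 1
            continue
        for a, b in _choice_pairs(content, rule):
            c = list(content)
            c[a], c[b] = c[b], c[a]
            c = tuple(c)
            new_z = tuple(c[x] == c[y] for x, y in _SEGREGATIONS)
            new_t = tuple(
                t + (1 if nz != z else 0) for t, nz, z in zip(trans, new_z, zyg)
            )
            stack.append((c, new_z, new_t, depth + 1))
    total = 4**k * 4
    outcomes = tuple(
        (key, Fraction(n, total)) for key, n in sorted(tallies.items())
    )
    e_det = sum((Fraction(key[0]) * w for key, w in outcomes), Fraction(0))
    e_det2 = sum((Fraction(key[0] ** 2) * w for key, w in outcomes), Fraction(0))
    e_term = sum((Fraction(key[1]) * w for key, w in outcomes), Fraction(0))
    e_inter = sum((Fraction(key[2]) * w for key, w in outcomes), Fraction(0))
    return DetectionResult(
        k=k,
        rule=rule,
        p_detect=e_det / k,
        e_detected=e_det,
        e_terminal=e_term,
        e_interstitial=e_inter,
        var_detected=e_det2 - e_det**2,
        outcomes=outcomes,
    )


def _detection_expectations(k: int, rule: str) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (E[detected], E[terminal], E[interstitial]) by dynamic programming.

    Tracks the distribution over the four-chromatid distal-content vector
    (six states) and accumulates, for each segregation, the probability of a
    zygosity change at every CO step; equivalent to full enumeration because
    the pair-choice law depends only on the current content vector.
    """
    e_det = Fraction(0)
    e_term = Fraction(0)
    for s in _SEGREGATIONS:
        dist: dict[tuple[int, ...], Fraction] = {_INITIAL: Fraction(1)}
        e_t = Fraction(0)
        for _ in range(k):
            new: dict[tuple[int, ...], Fraction] = {}
            for content, p in dist.items():
                z = content[s[0]] == content[s[1]]
                pairs = _choice_pairs(content, rule)
                w = p / len(pairs)
                for a, b in pairs:
                    c = list(content)
                    c[a], c[b] = c[b], c[a]
                    c = tuple(c)
                    if (c[s[0]] == c[s[1]]) != z:
                        e_t += w
                    new[c] = new.get(c, Fraction(0)) + w
            dist = new
        e_det += e_t
        e_term += sum(
            (p for content, p in dist.items() if content[s[0]] == content[s[1]]),
            Fraction(0),
        )
    e_det /= 4
    e_term /= 4
    return e_det, e_term, (e_det - e_term) / 2


def detection_table(max_k: int = 10, rule: str = OPPOSITE_CONTENT) -> pd.DataFrame:
    """Exact per-k detection probabilities for 1..max_k COs per arm.

    Columns: ``k``, ``p_detect`` (float), ``percent`` (rounded to one
    decimal), ``e_terminal``, ``e_interstitial``.
    """
    rows = []
    for k in range(1, max_k + 1):
        e_det, e_term, e_inter = _detection_expectations(k, rule)
        p = e_det / k
        rows.append(
            {
                "k": k,
                "p_detect": float(p),
                "percent": round(100 * float(p), 1),
                "e_terminal": float(e_term),
                "e_interstitial": float(e_inter),
            }
        )
    return pd.DataFrame(rows)


def detection_probability(k: int, rule: str = OPPOSITE_CONTENT) -> Fraction:
    """Exact detection probability for ``k`` COs on one arm."""
    e_det, _, _ = _detection_expectations(k, rule)
    return e_det / k


def sample_detection(
    k: int,
    n_draws: int,
    rng: np.random.Generator,
    rule: str = OPPOSITE_CONTENT,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the detection probability (estimate, std. error).

    Samples the same generative model as :func:`enumerate_detection`;
    included as an independent cross-check of the exact enumeration.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    content = np.tile(np.array(_INITIAL, dtype=np.int8), (n_draws, 1))
    a = rng.integers(0, 2, size=n_draws)
    b = 2 + rng.integers(0, 2, size=n_draws)
    rows = np.arange(n_draws)
    z = content[rows, a] == content[rows, b]
    transitions = np.zeros(n_draws, dtype=np.int32)
    all_pairs = np.array(
        [(x, y) for x in range(4) for y in range(x + 1, 4)], dtype=np.int8
    )
    for _ in range(k):
        if rule == INTER_HOMOLOG:
            choice = rng.integers(0, 4, size=n_draws)
            px = np.array(_INTER_HOMOLOG_PAIRS, dtype=np.int8)[choice]
        else:
            opp = content[:, all_pairs[:, 0]] != content[:, all_pairs[:, 1]]  # (n, 6)
            r = rng.integers(0, 4, size=n_draws)
            order = np.cumsum(opp, axis=1) - 1
            sel = np.argmax(order == r[:, None], axis=1)
            px = all_pairs[sel]
        x, y = px[:, 0], px[:, 1]
        cx = content[rows, x].copy()
        content[rows, x] = content[rows, y]
        content[rows, y] = cx
        z_new = content[rows, a] == content[rows, b]
        transitions += z_new != z
        z = z_new
    detected = transitions / k
    return float(detected.mean()), float(detected.std(ddof=1) / np.sqrt(n_draws))


# ------------------------------------------------------- expected detection
def expected_detection_frequency(
    arm_co_counts, table: pd.DataFrame | None = None, rule: str = OPPOSITE_CONTENT
) -> float:
    """CO-weighted mean detection probability for a per-arm CO distribution.

    ``arm_co_counts`` is either a mapping {k: number of arms with k COs} or
    an iterable of per-arm CO counts (each >= 1).  Returns a percentage:
    ``100 * sum(k * p(k) * n_arms(k)) / sum(k * n_arms(k))``.
    """
    if isinstance(arm_co_counts, dict):
        items = [(int(k), int(n)) for k, n in arm_co_counts.items() if n]
    else:
        counts: dict[int, int] = {}
        for k in arm_co_counts:
            counts[int(k)] = counts.get(int(k), 0) + 1
        items = sorted(counts.items())
    if not items:
        raise ValueError("no chromosome arms with crossovers supplied")
    if any(k < 1 for k, _ in items):
        raise ValueError("per-arm CO counts must be >= 1")
    if table is not None:
        probs = dict(zip(table["k"], table["p_detect"]))
        missing = [k for k, _ in items if k not in probs]
        if missing:
            raise ValueError(f"detection table does not cover k={missing}")
        p = {k: Fraction(probs[k]).limit_denominator(10**9) for k, _ in items}
    else:
        p = {k: detection_probability(k, rule) for k, _ in items}
    num = sum(Fraction(k * n) * p[k] for k, n in items)
    den = sum(k * n for k, n in items)
    return float(100 * num / den)


# ------------------------------------------------------------ count correction
@dataclass(frozen=True)
class CorrectionParams:
    """Detection-probability bounds and GC-association rate for corrections."""

    p_low: float = 0.5  # detection probability with one CO per arm
    p_high: float = 2.0 / 3.0  # asymptotic detection probability
    gc_frac: float = 0.81  # fraction of observed COs with an adjacent GC

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low <= self.p_high <= 1.0):
            raise ValueError("require 0 < p_low <= p_high <= 1")
        if not (0.0 <= self.gc_frac <= 1.0):
            raise ValueError("gc_frac must be in [0, 1]")


@dataclass(frozen=True)
class CorrectedCounts:
    """Ranges implied by the detection-probability bounds (low, high)."""

    observed_co: int
    observed_nrloh: int
    co: tuple[int, int]
    gc_co: tuple[int, int]
    nco: tuple[int, int]
    nco_co_ratio: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "observed_co": self.observed_co,
            "observed_nrloh": self.observed_nrloh,
            "corrected_co": list(self.co),
            "corrected_gc_co": list(self.gc_co),
            "corrected_nco": list(self.nco),
            "nco_co_ratio": list(self.nco_co_ratio),
        }


def _round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def correct_counts(
    observed_co: int,
    observed_nrloh: int,
    params: CorrectionParams | None = None,
) -> CorrectedCounts:
    """Correct observed CO/nrLOH counts for undetected (masked) crossovers.

    The true CO count lies between ``observed / p_high`` and
    ``observed / p_low``; the GC-associated CO range is ``gc_frac`` times
    that, and the NCO range is the observed nrLOH count minus the
    GC-associated COs (paired so that the low NCO bound uses the high GC-CO
    bound).  The NCO/CO fold-excess pairs the low NCO bound with the high CO
    bound.  All counts are rounded to the nearest integer.
    """
    if params is None:
        params = CorrectionParams()
    if observed_co < 0 or observed_nrloh < 0:
        raise ValueError("counts must be non-negative")
    co_lo = _round_half_up(observed_co / params.p_high)
    co_hi = _round_half_up(observed_co / params.p_low)
    gc_lo = _round_half_up(params.gc_frac * co_lo)
    gc_hi = _round_half_up(params.gc_frac * co_hi)
    nco_lo = observed_nrloh - gc_hi
    nco_hi = observed_nrloh - gc_lo
    ratio_lo = nco_lo / co_hi if co_hi else float("inf") if nco_lo else float("nan")
    ratio_hi = nco_hi / co_lo if co_lo else float("inf") if nco_hi else float("nan")
    if observed_co == 0:
        ratio_lo = ratio_hi = float("nan")
    return CorrectedCounts(
        observed_co=observed_co,
        observed_nrloh=observed_nrloh,
        co=(co_lo, co_hi),
        gc_co=(gc_lo, gc_hi),
        nco=(nco_lo, nco_hi),
        nco_co_ratio=(ratio_lo, ratio_hi),
    )


def compare_detection_rates(
    detected: int, masked: int, expected_percent: float
) -> tuple[float, float]:
    """Observed CO detection frequency vs an expected one.

    Returns ``(observed_percent, p_value)`` where the p-value comes from a
    two-sided Fisher exact test on the 2x2 table contrasting the observed
    detected/masked split with the expected split applied to the same total.
    """
    if detected < 0 or masked < 0:
        raise ValueError("counts must be non-negative")
    total = detected + masked
    if total == 0:
        raise ValueError("detected and masked cannot both be zero")
    observed = 100.0 * detected / total
    exp_detected = _round_half_up(total * expected_percent / 100.0)
    table = np.array([[detected, masked], [exp_detected, total - exp_detected]])
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return observed, float(p_value)
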