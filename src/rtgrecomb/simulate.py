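"""Synthetic RTG-meiosis generator with recorded ground truth.

Emulates the data produced by genotyping a two-parent hybrid yeast diploid
after a return-to-growth (RTG) event: a dense hybrid marker map (~0.7%
divergence, mean inter-marker spacing 191 bp), per-cell crossovers and gene
conversions placed on the four chromatids of a meiotic cell, equational
segregation into a mother and a daughter diploid, read-depth sampling with
sequencing error, sporulation of an RTG diploid into a four-spore tetrad,
and iterated RTG pedigrees.

Every stochastic choice (CO sites, chromatid pairs, conversion tracts,
segregations) is recorded in a :class:`SimTruth` that can be deterministically
replayed, and projected onto the list of events an ideal caller should
report given the recorded segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import INTER_HOMOLOG, OPPOSITE_CONTENT
from .events import CO, CO_GC, NCO, TERMINAL_NCO
from .genotypes import HET, HOM_P1, HOM_P2
from .loh import THREE_ONE, TWO_TWO_HOM, classify_segregation_vectors
from .markers import Chromosome, LEFT_ARM, MarkerMap, RIGHT_ARM

_BASES = np.array(list("ACGT"))


def yeast_chromosomes() -> list[Chromosome]:
    """The sixteen S. cerevisiae chromosomes with approximate centromere intervals."""
    data = [
        ("chrI", 230_218, 151_465, 151_582),
        ("chrII", 813_184, 238_207, 238_323),
        ("chrIII", 316_620, 114_385, 114_501),
        ("chrIV", 1_531_933, 449_711, 449_821),
        ("chrV", 576_874, 151_987, 152_104),
        ("chrVI", 270_161, 148_510, 148_627),
        ("chrVII", 1_090_940, 496_920, 497_038),
        ("chrVIII", 562_643, 105_586, 105_703),
        ("chrIX", 439_888, 355_629, 355_745),
        ("chrX", 745_751, 436_307, 436_425),
        ("chrXI", 666_816, 440_129, 440_246),
        ("chrXII", 1_078_177, 150_828, 150_947),
        ("chrXIII", 924_431, 268_031, 268_149),
        ("chrXIV", 784_333, 628_758, 628_875),
        ("chrXV", 1_091_291, 326_584, 326_702),
        ("chrXVI", 948_066, 555_957, 556_073),
    ]
    return [Chromosome(*row) for row in data]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the hybrid/RTG regime the package targets: marker
    spacing 191 bp; ~0.7 crossovers and ~1.3 independent conversion events
    per chromosome arm per RTG (about 22 true COs and 42 NCOs per cell over
    32 arms); 81% of COs carry an adjacent conversion tract; conversion
    tract lengths gamma-distributed with mean 2.3 kb; crossovers excluded
    within 10 kb of the centromere.  Sporulation of an RTG diploid uses the
    higher event rates of a complete meiosis (~2.3 COs and ~0.85 NCOs per
    arm, i.e. roughly 73 COs and 27 NCOs per tetrad).
    """

    chromosomes: list[Chromosome] = field(default_factory=yeast_chromosomes)
    marker_spacing: float = 191.0
    co_per_arm_mean: float = 0.7
    co_per_arm_fixed: int | None = None  # overrides the Poisson draw when set
    nco_per_arm_mean: float = 1.3
    gc_with_co: float = 0.81
    gc_len_mean: float = 2300.0
    gc_len_shape: float = 2.0
    cen_exclusion: int = 10_000
    telomere_exclusion: int = 15_000
    pairing_rule: str = OPPOSITE_CONTENT
    depth_mean: float = 50.0
    error_rate: float = 0.005
    premeiotic_4_0_rate: float = 0.0
    spo_co_per_arm_mean: float = 2.3
    spo_nco_per_arm_mean: float = 0.85

    def __post_init__(self) -> None:
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        for p in (self.gc_with_co, self.error_rate, self.premeiotic_4_0_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pairing_rule not in (OPPOSITE_CONTENT, INTER_HOMOLOG):
            raise ValueError(f"unknown pairing rule: {self.pairing_rule}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["chromosomes"] = [asdict(c) for c in self.chromosomes]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["chromosomes"] = [Chromosome(**c) for c in d.get("chromosomes", [])]
        return cls(**d)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------------ marker map
def make_marker_map(config: SimConfig, seed) -> MarkerMap:
    """Draw a hybrid marker map with exponential inter-marker spacing.

    Marker positions follow a Poisson process with the configured mean
    spacing; no marker falls inside a centromere interval.  Parental allele
    labels are random distinct bases.  Deterministic for a given seed.
    """
    rng = _rng(seed)
    chrom_idx = []
    pos = []
    for ci, chrom in enumerate(config.chromosomes):
        if config.marker_spacing >= chrom.length:
            raise ValueError(f"{chrom.name}: marker spacing exceeds chromosome length")
        n_draw = int(chrom.length / config.marker_spacing * 1.6) + 16
        gaps = rng.exponential(config.marker_spacing, size=n_draw)
        p = np.unique(np.ceil(np.cumsum(gaps)).astype(np.int64))
        p = p[(p >= 1) & (p <= chrom.length)]
        p = p[(p < chrom.cen_start) | (p > chrom.cen_end)]
        chrom_idx.append(np.full(p.size, ci, dtype=np.int32))
        pos.append(p)
    chrom_idx = np.concatenate(chrom_idx)
    pos = np.concatenate(pos)
    p1 = _BASES[rng.integers(0, 4, size=pos.size)]
    offset = 1 + rng.integers(0, 3, size=pos.size)
    p2 = _BASES[(np.searchsorted(_BASES, p1) + offset) % 4]
    return MarkerMap(config.chromosomes, chrom_idx, pos, p1, p2)


# ------------------------------------------------------------------ sim events
@dataclass
class SimEvent:
    """One recorded recombination event, replayable without randomness.

    For a CO, ``gap`` holds the global indices of the two markers flanking
    the exchange point (proximal flank first in arm orientation) and
    ``pair`` the chromatids that exchanged distal content; ``gc`` is the
    inclusive marker-index range of the adjacent conversion tract (or None)
    with ``recipient`` the converted chromatid.  For an NCO, ``gc`` is the
    converted tract and ``pair`` is (donor, recipient).
    """

    kind: str  # "CO" | "NCO"
    chrom: str
    arm: int
    gap: tuple[int, int] | None
    pair: tuple[int, int]
    gc: tuple[int, int] | None = None
    recipient: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "chrom": self.chrom,
            "arm": self.arm,
            "gap": list(self.gap) if self.gap else None,
            "pair": list(self.pair),
            "gc": list(self.gc) if self.gc else None,
            "recipient": self.recipient,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimEvent":
        return cls(
            kind=d["kind"],
            chrom=d["chrom"],
            arm=int(d["arm"]),
            gap=tuple(d["gap"]) if d["gap"] else None,
            pair=tuple(d["pair"]),
            gc=tuple(d["gc"]) if d["gc"] else None,
            recipient=d["recipient"],
        )


@dataclass
class SimTruth:
    """Recorded events and segregation choices of one simulated RTG meiosis."""

    events: list[SimEvent]
    segregation: dict[str, tuple[int, int]]  # chrom -> (mother sister-0 pick, sister-1 pick)
    n_markers: int
    lineage: str = ""

    def to_json(self, path: str | Path) -> None:
        d = {
            "events": [e.to_dict() for e in self.events],
            "segregation": {k: list(v) for k, v in self.segregation.items()},
            "n_markers": self.n_markers,
            "lineage": self.lineage,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            events=[SimEvent.from_dict(e) for e in d["events"]],
            segregation={k: tuple(v) for k, v in d["segregation"].items()},
            n_markers=int(d["n_markers"]),
            lineage=d.get("lineage", ""),
        )


@dataclass
class RtgPair:
    """A simulated mother-daughter RTG pair with its ground truth."""

    mother: np.ndarray  # diploid genotype codes
    daughter: np.ndarray
    mother_haplotypes: np.ndarray  # (2, n) chromatid contents (0=P1, 1=P2)
    daughter_haplotypes: np.ndarray
    truth: SimTruth


# ----------------------------------------------------------- meiosis machinery
def _distal_slice(mmap: MarkerMap, ci: int, arm: int, gap: tuple[int, int]) -> slice:
    """Markers distal of a CO gap, as a contiguous global slice."""
    sl = mmap.chrom_slice(ci)
    if arm == RIGHT_ARM:
        return slice(gap[1], sl.stop)
    return slice(sl.start, gap[1] + 1)


def _plan_arm_events(
    mmap: MarkerMap,
    ci: int,
    arm: int,
    config: SimConfig,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    co_mean: float,
    nco_mean: float,
) -> list[SimEvent]:
    """Sample CO/NCO placements for one arm, avoiding event collisions.

    Crossover gaps are distinct inter-marker intervals outside the
    centromere exclusion radius; all event footprints (CO gap flanks plus
    conversion tract) are kept at least one marker apart so each event has
    an unambiguous signature.  Placement is resampled (up to a cap) when a
    draw collides; colliding events beyond the cap are dropped.
    """
    chrom = mmap.chromosomes[ci]
    name = chrom.name
    idx = mmap.arm_markers(ci, arm)  # proximal -> distal
    events: list[SimEvent] = []
    if idx.size == 0:
        return events
    pos = mmap.pos[idx]
    cen_edge = chrom.cen_start if arm == LEFT_ARM else chrom.cen_end
    end_pos = 1 if arm == LEFT_ARM else chrom.length
    # events are anchored away from the centromere (DSB depletion) and from
    # the chromosome ends (subtelomeric regions are not genotyped in the
    # data this emulates, and terminal conversions are unresolvable)
    far_enough = (np.abs(pos - cen_edge) > config.cen_exclusion) & (
        np.abs(end_pos - pos) > config.telomere_exclusion
    )

    def overlaps(lo: int, hi: int) -> bool:
        return any(lo <= b + 1 and a - 1 <= hi for a, b in occupied)

    def gc_range(anchor_pos: int, length: float, toward_distal: bool) -> tuple[int, int] | None:
        """Inclusive global marker-index range of a conversion tract."""
        sl = mmap.chrom_slice(ci)
        cpos = mmap.pos[sl]
        distal_is_up = arm == RIGHT_ARM
        if toward_distal == distal_is_up:
            lo_bp, hi_bp = anchor_pos, anchor_pos + length
        else:
            lo_bp, hi_bp = anchor_pos - length, anchor_pos
        a = int(np.searchsorted(cpos, lo_bp, side="left"))
        b = int(np.searchsorted(cpos, hi_bp, side="right")) - 1
        if b < a:
            return None
        lo, hi = sl.start + a, sl.start + b
        # clamp to this arm
        arm_lo, arm_hi = min(idx[0], idx[-1]), max(idx[0], idx[-1])
        lo, hi = max(lo, arm_lo), min(hi, arm_hi)
        return (lo, hi) if lo <= hi else None

    # --- crossovers
    n_gaps = idx.size - 1
    gap_ok = far_enough[:-1] if n_gaps > 0 else np.zeros(0, dtype=bool)
    candidates = np.flatnonzero(gap_ok)
    if config.co_per_arm_fixed is not None:
        k = config.co_per_arm_fixed
    else:
        k = int(rng.poisson(co_mean))
    k = min(k, candidates.size)
    for _ in range(k):
        for _try in range(200):
            g = int(candidates[rng.integers(candidates.size)])
            prox, dist = int(idx[g]), int(idx[g + 1])
            lo, hi = min(prox, dist), max(prox, dist)
            has_gc = rng.random() < config.gc_with_co
            gc = None
            recipient = None
            if has_gc:
                length = rng.gamma(config.gc_len_shape, config.gc_len_mean / config.gc_len_shape)
                toward_distal = bool(rng.integers(2))
                anchor = int((mmap.pos[lo] + mmap.pos[hi]) // 2)
                gc = gc_range(anchor, length, toward_distal)
                if gc is not None:
                    # the conversion tract sits on one side of the exchange
                    # point: clamp it so it never crosses the CO gap
                    side_idx = dist if toward_distal else prox
                    if side_idx >= max(prox, dist):
                        gc = (max(gc[0], side_idx), gc[1])
                    else:
                        gc = (gc[0], min(gc[1], side_idx))
                    if gc[0] > gc[1]:
                        gc = None
                recipient = int(rng.integers(2))  # index into the CO pair
            flo = min(lo, gc[0]) if gc else lo
            fhi = max(hi, gc[1]) if gc else hi
            if not overlaps(flo, fhi):
                occupied.append((flo, fhi))
                events.append(
                    SimEvent(
                        kind="CO",
                        chrom=name,
                        arm=arm,
                        gap=(prox, dist),
                        pair=(-1, -1),  # resolved at application time
                        gc=gc,
                        recipient=recipient,
                    )
                )
                break

    # --- independent conversion events (NCOs)
    n_nco = int(rng.poisson(nco_mean))
    arm_far = idx[far_enough]
    for _ in range(n_nco):
        if arm_far.size == 0:
            break
        for _try in range(200):
            center = int(mmap.pos[arm_far[rng.integers(arm_far.size)]])
            length = rng.gamma(config.gc_len_shape, config.gc_len_mean / config.gc_len_shape)
            lo_hi = gc_range(center + int(length // 2), length, toward_distal=False)
            if lo_hi is None:
                continue
            if not overlaps(*lo_hi):
                occupied.append(lo_hi)
                events.append(
                    SimEvent(
                        kind="NCO",
                        chrom=name,
                        arm=arm,
                        gap=None,
                        pair=(-1, -1),
                        gc=lo_hi,
                        recipient=None,
                    )
                )
                break

    # COs are applied proximal -> distal
    def order_key(e: SimEvent):
        if e.kind == "CO":
            anchor = e.gap[0]
        else:
            anchor = e.gc[0]
        return abs(int(mmap.pos[anchor]) - cen_edge)

    events.sort(key=lambda e: (e.kind != "CO", order_key(e)))
    return events


def _apply_events(
    chromatids: np.ndarray,
    events: list[SimEvent],
    mmap: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator | None,
) -> None:
    """Apply planned events to the four chromatids, resolving free choices.

    When ``rng`` is None the events must already carry resolved chromatid
    choices (replay mode).
    """
    for e in events:
        ci = mmap.chrom_index(e.chrom)
        if e.kind == "CO":
            dist_sl = _distal_slice(mmap, ci, e.arm, e.gap)
            if rng is not None:
                probe = e.gap[1]  # immediate distal flank
                c = chromatids[:, probe]
                if config.pairing_rule == INTER_HOMOLOG:
                    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
                else:
                    pairs = [
                        (a, b) for a in range(4) for b in range(a + 1, 4) if c[a] != c[b]
                    ] or [(0, 2), (0, 3), (1, 2), (1, 3)]
                e.pair = pairs[int(rng.integers(len(pairs)))]
            x, y = e.pair
            tmp = chromatids[x, dist_sl].copy()
            chromatids[x, dist_sl] = chromatids[y, dist_sl]
            chromatids[y, dist_sl] = tmp
            if e.gc is not None:
                recip = e.pair[e.recipient]
                donor = e.pair[1 - e.recipient]
                lo, hi = e.gc
                chromatids[recip, lo : hi + 1] = chromatids[donor, lo : hi + 1]
        else:  # NCO
            lo, hi = e.gc
            if rng is not None:
                c = chromatids[:, lo]
                pairs = [
                    (a, b) for a in range(4) for b in range(a + 1, 4) if c[a] != c[b]
                ] or [(0, 2), (0, 3), (1, 2), (1, 3)]
                donor, recip = pairs[int(rng.integers(len(pairs)))]
                if rng.integers(2):
                    donor, recip = recip, donor
                e.pair = (donor, recip)
            donor, recip = e.pair
            chromatids[recip, lo : hi + 1] = chromatids[donor, lo : hi + 1]


def _meiosis(
    haplotypes: np.ndarray,
    mmap: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
    co_mean: float,
    nco_mean: float,
) -> tuple[np.ndarray, list[SimEvent]]:
    """Replicate two haplotypes into four chromatids and recombine them."""
    chromatids = np.vstack(
        [haplotypes[0], haplotypes[0], haplotypes[1], haplotypes[1]]
    ).astype(np.int8)
    all_events: list[SimEvent] = []
    for ci in range(len(mmap.chromosomes)):
        occupied: list[tuple[int, int]] = []
        chrom_events: list[SimEvent] = []
        for arm in (LEFT_ARM, RIGHT_ARM):
            chrom_events.extend(
                _plan_arm_events(mmap, ci, arm, config, rng, occupied, co_mean, nco_mean)
            )
        _apply_events(chromatids, chrom_events, mmap, config, rng)
        all_events.extend(chrom_events)
    if config.premeiotic_4_0_rate > 0:
        _apply_premeiotic(chromatids, mmap, config, rng)
    return chromatids, all_events


def _apply_premeiotic(
    chromatids: np.ndarray, mmap: MarkerMap, config: SimConfig, rng: np.random.Generator
) -> None:
    """Rare premeiotic conversions: both sisters of one homolog converted (4:0)."""
    n = mmap.n_markers
    hit = rng.random(n) < config.premeiotic_4_0_rate
    for m in np.flatnonzero(hit):
        if rng.integers(2):
            chromatids[0:2, m] = chromatids[2, m]
        else:
            chromatids[2:4, m] = chromatids[0, m]


def simulate_rtg_pair(
    mmap: MarkerMap,
    config: SimConfig,
    seed,
    haplotypes: np.ndarray | None = None,
    segregation: dict[str, tuple[int, int]] | None = None,
) -> RtgPair:
    """Simulate one RTG meiosis and the resulting mother/daughter diploids.

    ``haplotypes`` (2, n_markers; contents 0/1) defaults to the pristine
    hybrid (all-heterozygous) state.  ``segregation`` may pin the equational
    segregation per chromosome: ``(i, j)`` sends sister-pair-one chromatid
    ``i`` (0/1) and sister-pair-two chromatid ``j`` (2/3) to the mother.
    """
    rng = _rng(seed)
    n = mmap.n_markers
    if haplotypes is None:
        haplotypes = np.vstack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    chromatids, events = _meiosis(
        haplotypes, mmap, config, rng, config.co_per_arm_mean, config.nco_per_arm_mean
    )
    seg: dict[str, tuple[int, int]] = {}
    mother = np.empty(n, dtype=np.int8)
    daughter = np.empty(n, dtype=np.int8)
    m_h = np.empty((2, n), dtype=np.int8)
    d_h = np.empty((2, n), dtype=np.int8)
    for ci, chrom in enumerate(mmap.chromosomes):
        sl = mmap.chrom_slice(ci)
        if segregation is not None and chrom.name in segregation:
            a, b = segregation[chrom.name]
        else:
            a, b = int(rng.integers(2)), 2 + int(rng.integers(2))
        seg[chrom.name] = (a, b)
        m_h[0, sl] = chromatids[a, sl]
        m_h[1, sl] = chromatids[b, sl]
        d_h[0, sl] = chromatids[1 - a, sl]
        d_h[1, sl] = chromatids[5 - b, sl]
    mother = (m_h[0] + m_h[1]).astype(np.int8)
    daughter = (d_h[0] + d_h[1]).astype(np.int8)
    truth = SimTruth(events=events, segregation=seg, n_markers=n)
    return RtgPair(mother, daughter, m_h, d_h, truth)


def replay_truth(
    truth: SimTruth, mmap: MarkerMap, config: SimConfig, haplotypes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministically rebuild (chromatids, mother, daughter) from a truth record."""
    n = mmap.n_markers
    if haplotypes is None:
        haplotypes = np.vstack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    chromatids = np.vstack(
        [haplotypes[0], haplotypes[0], haplotypes[1], haplotypes[1]]
    ).astype(np.int8)
    _apply_events(chromatids, truth.events, mmap, config, rng=None)
    mother = np.empty(n, dtype=np.int8)
    daughter = np.empty(n, dtype=np.int8)
    for ci, chrom in enumerate(mmap.chromosomes):
        sl = mmap.chrom_slice(ci)
        a, b = truth.segregation[chrom.name]
        mother[sl] = chromatids[a, sl] + chromatids[b, sl]
        daughter[sl] = chromatids[1 - a, sl] + chromatids[5 - b, sl]
    return chromatids, mother, daughter


# -------------------------------------------------- expected observable events
@dataclass
class ExpectedEvent:
    """What an ideal caller should report for one truth event."""

    kind: str  # CO | CO_GC | NCO | TERMINAL_NCO
    chrom: str
    start_idx: int
    end_idx: int
    source_kind: str  # truth event kind: CO or NCO
    manifest: bool = True


def expected_events(
    truth: SimTruth, mmap: MarkerMap, config: SimConfig
) -> tuple[list[ExpectedEvent], dict]:
    """Project recorded truth onto the events observable in the diploid pair.

    A CO manifests iff the equational segregation changes the mother's
    zygosity across its breakpoint (tracked on the CO backbone, ignoring
    conversion tracts); conversion tracts always manifest as 3:1 runs when
    donor and recipient content differ.  Expected kinds mirror the caller's
    decision rules: a conversion tract marker-adjacent to a manifest rLOH
    span is a CO-associated GC; one inside an rLOH span or in heterozygous
    context is an NCO (terminal if it holds the arm's last marker).

    Returns the expected event list and a summary with true/manifest CO
    counts (the basis for detection-rate and correction checks).
    """
    chromatids, mother, daughter = replay_truth(truth, mmap, config)
    pat = classify_segregation_vectors(mother, daughter)
    expected: list[ExpectedEvent] = []
    n_true_co = 0
    n_manifest_co = 0
    arm_co_counts: list[int] = []
    rloh_spans: dict[str, list[tuple[int, int]]] = {}
    manifest_ids: set[int] = set()

    for ci, chrom in enumerate(mmap.chromosomes):
        name = chrom.name
        a, b = truth.segregation[name]
        spans = rloh_spans.setdefault(name, [])
        for arm in (LEFT_ARM, RIGHT_ARM):
            cos = [
                e
                for e in truth.events
                if e.chrom == name and e.arm == arm and e.kind == "CO"
            ]
            if cos:
                arm_co_counts.append(len(cos))
            n_true_co += len(cos)
            # backbone zygosity per inter-CO segment, proximal -> distal
            content = [0, 0, 1, 1]
            zyg = [content[a] == content[b]]
            for e in cos:  # already ordered proximal -> distal
                x, y = e.pair
                content[x], content[y] = content[y], content[x]
                zyg.append(content[a] == content[b])
            arm_idx = mmap.arm_markers(ci, arm)
            if arm_idx.size == 0:
                continue
            # segment boundaries in arm ordering
            seg_edges = [0]
            for e in cos:
                gpos = np.flatnonzero(arm_idx == e.gap[1])[0]
                seg_edges.append(int(gpos))
            seg_edges.append(arm_idx.size)
            for si in range(len(cos) + 1):
                manifest = si > 0 and zyg[si] != zyg[si - 1]
                if manifest:
                    n_manifest_co += 1
                    e = cos[si - 1]
                    manifest_ids.add(id(e))
                    lo, hi = sorted(e.gap)
                    expected.append(
                        ExpectedEvent(
                            kind=CO_GC if _gc_visible(e, chromatids) else CO,
                            chrom=name,
                            start_idx=lo,
                            end_idx=hi,
                            source_kind="CO",
                        )
                    )
                if not zyg[si]:  # homozygous segment -> expected rLOH span
                    seg_markers = arm_idx[seg_edges[si] : seg_edges[si + 1]]
                    hom = seg_markers[pat[seg_markers] == TWO_TWO_HOM]
                    if hom.size:
                        spans.append((int(hom.min()), int(hom.max())))

    # conversion tracts -> expected nrLOH events.  A manifest CO's tract is
    # folded into its CO_GC event above; a *masked* CO's tract still shows,
    # as an independent non-reciprocal tract indistinguishable from an NCO.
    for e in truth.events:
        if e.gc is None or id(e) in manifest_ids:
            continue
        lo, hi = e.gc
        if not np.any(pat[lo : hi + 1] == THREE_ONE):
            continue  # invisible conversion (donor content equalled recipient)
        vis = np.flatnonzero(pat[lo : hi + 1] == THREE_ONE)
        lo_v, hi_v = lo + int(vis[0]), lo + int(vis[-1])
        name = e.chrom
        spans = rloh_spans.get(name, [])
        inside = any(s <= lo_v and hi_v <= t for s, t in spans)
        adjacent = any(s <= hi_v + 1 and lo_v - 1 <= t for s, t in spans)
        ci = mmap.chrom_index(name)
        if inside:
            kind = NCO
        elif adjacent:
            kind = CO_GC
        else:
            terminal_marker = mmap.arm_terminal_marker(ci, e.arm)
            if terminal_marker is not None and lo_v <= terminal_marker <= hi_v:
                kind = TERMINAL_NCO
            else:
                kind = NCO
        expected.append(
            ExpectedEvent(kind=kind, chrom=name, start_idx=lo_v, end_idx=hi_v,
                          source_kind=e.kind)
        )

    summary = {
        "n_true_co": n_true_co,
        "n_manifest_co": n_manifest_co,
        "arm_co_counts": arm_co_counts,
        "rloh_spans": rloh_spans,
    }
    return expected, summary


def _gc_visible(e: SimEvent, chromatids: np.ndarray) -> bool:
    """Whether a conversion tract is observable as a 3:1 run.

    After application the donor and recipient chromatids are identical over
    the tract, so the conversion shows iff the tract markers carry three
    copies of one parental allele among the four chromatids.
    """
    if e.gc is None:
        return False
    lo, hi = e.gc
    counts = chromatids[:, lo : hi + 1].sum(axis=0)
    return bool(np.any((counts == 1) | (counts == 3)))


def match_expected_calls(called, expected: list[ExpectedEvent]) -> dict:
    """One-to-one matching of called events against the expected projection.

    A conversion event (NCO / TERMINAL_NCO, or the conversion half of a
    CO-GC) matches on exact marker span.  A crossover event matches when the
    expected breakpoint gap lies within the called event's marker interval
    extended by one marker on each side — the called interval is anchored on
    the rLOH tract edge and legitimately shifts by the adjacent conversion
    tract when the CO carries a GC.  Kinds must agree.  Returns precision /
    recall and the unmatched residue of both lists.
    """
    unmatched_called = list(called)
    unmatched_expected = list(expected)
    n_match = 0
    for exp in list(unmatched_expected):
        hit = None
        for ev in unmatched_called:
            if ev.chrom != exp.chrom or ev.kind != exp.kind:
                continue
            if exp.kind in (CO, CO_GC):
                if ev.start_idx - 1 <= exp.start_idx and exp.end_idx <= ev.end_idx + 1:
                    hit = ev
                    break
            else:
                if ev.start_idx == exp.start_idx and ev.end_idx == exp.end_idx:
                    hit = ev
                    break
        if hit is not None:
            unmatched_called.remove(hit)
            unmatched_expected.remove(exp)
            n_match += 1
    precision = n_match / len(called) if called else 1.0
    recall = n_match / len(expected) if expected else 1.0
    return {
        "n_matched": n_match,
        "precision": precision,
        "recall": recall,
        "unmatched_called": unmatched_called,
        "unmatched_expected": unmatched_expected,
    }


# ---------------------------------------------------------------- read sampling
def sample_reads(
    calls: np.ndarray, config: SimConfig, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-marker parental allele depths for a true genotype vector.

    Depth is Poisson with the configured mean.  Each read derives from one
    of the two chromosomes (fair coin at heterozygous markers) and reports
    the wrong parental allele with the configured error rate.  Returns
    ``(n_p1, n_p2)`` arrays.
    """
    rng = _rng(seed)
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.size
    depth = rng.poisson(config.depth_mean, size=n)
    p_p2 = np.where(calls == HET, 0.5, np.where(calls == HOM_P2, 1.0, 0.0))
    # a read reports P2 if it samples the P2 chromosome and is not flipped,
    # or samples P1 and is flipped
    e = config.error_rate
    p_read_p2 = p_p2 * (1 - e) + (1 - p_p2) * e
    n_p2 = rng.binomial(depth, p_read_p2)
    return (depth - n_p2).astype(np.int64), n_p2.astype(np.int64)


# ------------------------------------------------------------------ sporulation
def sporulate(
    haplotypes: np.ndarray,
    mmap: MarkerMap,
    config: SimConfig,
    seed,
    co_mean: float | None = None,
    nco_mean: float | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Sporulate a diploid into a four-spore tetrad.

    Runs a complete meiosis on the parent's two haplotypes: replication into
    four chromatids, fresh crossovers/conversions between homolog-crossing
    chromatid pairs at the configured sporulation rates, then the
    reductional and equational divisions deliver one chromatid per spore.
    Markers homozygous in the parent therefore segregate 4:0 and
    heterozygous markers 2:2 (3:1 inside new conversion tracts).

    Returns ``(spores, truth)`` where ``spores`` is a (4, n) array of
    haploid genotype codes (HOM_P1/HOM_P2).
    """
    rng = _rng(seed)
    if haplotypes.shape[0] != 2:
        raise ValueError("parent must be diploid (two haplotypes)")
    spo_config = replace(config, pairing_rule=INTER_HOMOLOG)
    chromatids, events = _meiosis(
        haplotypes,
        mmap,
        spo_config,
        rng,
        config.spo_co_per_arm_mean if co_mean is None else co_mean,
        config.spo_nco_per_arm_mean if nco_mean is None else nco_mean,
    )
    order = rng.permutation(4)
    spores = (chromatids[order] * 2).astype(np.int8)
    truth = SimTruth(
        events=events,
        segregation={c.name: (int(order[0]), int(order[1])) for c in mmap.chromosomes},
        n_markers=mmap.n_markers,
        lineage="tetrad",
    )
    return spores, truth


# --------------------------------------------------------------------- pedigree
@dataclass
class PassageRecord:
    passage: int
    pair: RtgPair
    followed: str  # "mother" | "daughter"
    hom_fraction: float


def simulate_pedigree(
    mmap: MarkerMap, config: SimConfig, passages: int, seed
) -> list[PassageRecord]:
    """Iterate the RTG process: each passage re-enters meiosis and returns to growth.

    Passage n+1 starts from the haplotypes of one strain of passage n (chosen
    at random), so LOH fixed at passage n persists in all descendants and the
    homozygous marker fraction is non-decreasing along the lineage.
    """
    if passages < 1:
        raise ValueError("passages must be >= 1")
    rng = _rng(seed)
    n = mmap.n_markers
    haps = np.vstack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    records: list[PassageRecord] = []
    for p in range(1, passages + 1):
        pair = simulate_rtg_pair(mmap, config, rng, haplotypes=haps)
        pair.truth.lineage = f"passage{p}"
        follow = "mother" if rng.integers(2) else "daughter"
        haps = pair.mother_haplotypes if follow == "mother" else pair.daughter_haplotypes
        calls = pair.mother if follow == "mother" else pair.daughter
        hom_frac = float(np.mean(calls != HET))
        records.append(PassageRecord(p, pair, follow, hom_frac))
    return records
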