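"""Diploid genotype calling from parental allele depths.

Calls each SNP marker of a hybrid diploid as homozygous-P1, homozygous-P2,
heterozygous or no-call from the read counts supporting each parental allele.
The thresholds are asymmetric — biased toward the reference-like P1 parent —
because reads are assumed mapped against the P1-derived reference, which
inflates the apparent P1 allele fraction.  A run-length filter then removes
genotype switches supported by fewer than a minimum number of adjacent
markers, which guards against read-ratio bias turning isolated heterozygous
markers into spurious homozygous calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerMap

# Genotype codes.  HOM_P1 + HOM_P2 = 2 * HET, so the diploid genotype of a
# marker equals the sum of its two haplotype contents (P1 content = 0,
# P2 content = 1); several modules rely on this arithmetic.
NO_CALL = np.int8(-1)
HOM_P1 = np.int8(0)
HET = np.int8(1)
HOM_P2 = np.int8(2)

GENOTYPE_LABELS = {int(NO_CALL): "NA", int(HOM_P1): "P1", int(HET): "HET", int(HOM_P2): "P2"}
LABEL_TO_CODE = {v: np.int8(k) for k, v in GENOTYPE_LABELS.items()}


@dataclass(frozen=True)
class GenotypingThresholds:
    """Allele-fraction thresholds for diploid genotype calls.

    ``min_depth_exclusive`` is a strict bound: a marker is callable only when
    total coverage is *greater than* this many reads.  ``min_parental_fraction``
    is the minimum fraction of reads carrying either parental allele (relevant
    only when non-parental read counts are supplied).  Homozygous cutoffs are
    strict (``>``); the heterozygous ranges are inclusive.
    """

    min_depth_exclusive: int = 5
    min_parental_fraction: float = 2.0 / 3.0
    p1_hom_min: float = 0.95
    p2_hom_min: float = 0.75
    het_p1_range: tuple[float, float] = (0.25, 0.95)
    het_p2_range: tuple[float, float] = (0.05, 0.75)
    min_adjacent_switch: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.p2_hom_min < self.p1_hom_min < 1.0):
            raise ValueError("require 0 < p2_hom_min < p1_hom_min < 1")
        lo1, hi1 = self.het_p1_range
        lo2, hi2 = self.het_p2_range
        if not (0.0 <= lo1 < hi1 <= 1.0 and 0.0 <= lo2 < hi2 <= 1.0):
            raise ValueError("malformed heterozygous ranges")
        if abs(hi1 - self.p1_hom_min) > 1e-9 or abs(hi2 - self.p2_hom_min) > 1e-9:
            raise ValueError("het range upper bounds must equal the homozygous cutoffs")
        if self.min_adjacent_switch < 1:
            raise ValueError("min_adjacent_switch must be >= 1")


DEFAULT_THRESHOLDS = GenotypingThresholds()


def call_genotypes(
    n_p1: np.ndarray,
    n_p2: np.ndarray,
    n_other: np.ndarray | int = 0,
    thresholds: GenotypingThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised genotype call per marker.

    Parameters
    ----------
    n_p1, n_p2:
        Read counts supporting each parental allele.
    n_other:
        Reads supporting neither parental allele (sequencing errors, third
        alleles); enters only the parental-fraction rule.

    Returns
    -------
    int8 array of genotype codes (``HOM_P1``/``HET``/``HOM_P2``/``NO_CALL``).
    """
    n_p1 = np.asarray(n_p1, dtype=np.int64)
    n_p2 = np.asarray(n_p2, dtype=np.int64)
    n_other = np.broadcast_to(np.asarray(n_other, dtype=np.int64), n_p1.shape)
    if np.any(n_p1 < 0) or np.any(n_p2 < 0) or np.any(n_other < 0):
        raise ValueError("negative read counts")

    t = thresholds
    parental = n_p1 + n_p2
    total = parental + n_other
    callable_ = (total > t.min_depth_exclusive) & (parental > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        callable_ &= parental >= t.min_parental_fraction * total - 1e-9
        f1 = np.where(parental > 0, n_p1 / np.maximum(parental, 1), 0.0)
    f2 = 1.0 - f1

    out = np.full(n_p1.shape, NO_CALL, dtype=np.int8)
    out[callable_ & (f1 > t.p1_hom_min)] = HOM_P1
    out[callable_ & (f2 > t.p2_hom_min)] = HOM_P2
    is_het = (
        callable_
        & (f1 >= t.het_p1_range[0])
        & (f1 <= t.het_p1_range[1])
        & (f2 >= t.het_p2_range[0])
        & (f2 <= t.het_p2_range[1])
        & (out == NO_CALL)
    )
    out[is_het] = HET
    return out


def call_genotype(
    n_p1: int,
    n_p2: int,
    n_other: int = 0,
    thresholds: GenotypingThresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Genotype call for a single marker (scalar convenience wrapper)."""
    return int(call_genotypes(np.array([n_p1]), np.array([n_p2]), np.array([n_other]), thresholds)[0])


# --------------------------------------------------------------- run filtering
def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a 1-D array as (start, stop, value), stop exclusive."""
    if values.size == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [values.size]))
    return [(int(a), int(b), int(values[a])) for a, b in zip(starts, stops)]


def filter_short_runs(
    calls: np.ndarray,
    min_adjacent_switch: int = 3,
    symmetric: bool = False,
) -> tuple[np.ndarray, list[dict]]:
    """Remove genotype switches supported by too few adjacent markers.

    A maximal run of homozygous calls shorter than ``min_adjacent_switch``
    whose flanking called neighbours are heterozygous (or absent, at
    chromosome ends) is reassigned to HET.  NO_CALL markers are transparent:
    they neither break runs nor count toward run length.  With
    ``symmetric=True`` short HET runs embedded in a uniform homozygous
    context are likewise reassigned (off by default).

    The pass is idempotent and never creates a new homozygous run.  Returns
    the filtered copy and a log of reassignments.
    """
    calls = np.asarray(calls, dtype=np.int8)
    out = calls.copy()
    log: list[dict] = []
    called_idx = np.flatnonzero(calls != NO_CALL)
    if called_idx.size == 0:
        return out, log
    condensed = calls[called_idx]
    runs = _runs(condensed)
    for ri, (a, b, val) in enumerate(runs):
        length = b - a
        if length >= min_adjacent_switch:
            continue
        left = runs[ri - 1][2] if ri > 0 else None
        right = runs[ri + 1][2] if ri + 1 < len(runs) else None
        if val in (int(HOM_P1), int(HOM_P2)):
            if left in (None, int(HET)) and right in (None, int(HET)):
                new_val = HET
            else:
                continue
        elif symmetric and val == int(HET):
            hom_ctx = {left, right} - {None}
            if len(hom_ctx) == 1 and hom_ctx <= {int(HOM_P1), int(HOM_P2)}:
                new_val = np.int8(hom_ctx.pop())
            else:
                continue
        else:
            continue
        orig = called_idx[a:b]
        out[orig] = new_val
        log.append(
            {
                "start": int(orig[0]),
                "stop": int(orig[-1]) + 1,
                "n_markers": length,
                "from": GENOTYPE_LABELS[val],
                "to": GENOTYPE_LABELS[int(new_val)],
            }
        )
    return out, log


def filter_short_runs_map(
    calls: np.ndarray,
    marker_map: MarkerMap,
    min_adjacent_switch: int = 3,
    symmetric: bool = False,
) -> tuple[np.ndarray, list[dict]]:
    """Apply :func:`filter_short_runs` independently to each chromosome."""
    out = np.asarray(calls, dtype=np.int8).copy()
    log: list[dict] = []
    for ci in range(len(marker_map.chromosomes)):
        sl = marker_map.chrom_slice(ci)
        filt, sub = filter_short_runs(out[sl], min_adjacent_switch, symmetric)
        out[sl] = filt
        for entry in sub:
            entry = dict(entry)
            entry["chrom"] = marker_map.chrom_name(ci)
            entry["start"] += sl.start
            entry["stop"] += sl.start
            log.append(entry)
    return out, log


# ------------------------------------------------------------------- marker QC
QC_KEEP = "keep"
QC_REASONS = {
    "parent1_not_hom_p1": "parent 1 not homozygous P1",
    "parent2_not_hom_p2": "parent 2 not homozygous P2",
    "shared_allele": "both parents carry the same homozygous genotype",
    "hybrid_not_het": "hybrid not heterozygous",
}


def qc_marker_set(
    parent1: np.ndarray, parent2: np.ndarray, hybrid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Retain markers with the expected control genotypes.

    A marker is kept iff parent 1 is homozygous P1, parent 2 homozygous P2 and
    the hybrid heterozygous.  Returns a boolean mask and a per-marker reason
    code (``"keep"`` for retained markers).
    """
    parent1 = np.asarray(parent1, dtype=np.int8)
    parent2 = np.asarray(parent2, dtype=np.int8)
    hybrid = np.asarray(hybrid, dtype=np.int8)
    if not (parent1.shape == parent2.shape == hybrid.shape):
        raise ValueError("genotype vectors have mismatched lengths")
    keep = (parent1 == HOM_P1) & (parent2 == HOM_P2) & (hybrid == HET)
    reasons = np.full(parent1.shape, QC_KEEP, dtype=object)
    shared = (parent1 == parent2) & (parent1 != NO_CALL) & (parent1 != HET)
    reasons[~keep & (parent1 != HOM_P1)] = "parent1_not_hom_p1"
    reasons[~keep & (parent2 != HOM_P2)] = "parent2_not_hom_p2"
    reasons[shared] = "shared_allele"
    reasons[~keep & (parent1 == HOM_P1) & (parent2 == HOM_P2) & (hybrid != HET)] = (
        "hybrid_not_het"
    )
    return keep, reasons


# ------------------------------------------------------------ coverage windows
def coverage_windows(
    depth: pd.DataFrame,
    window: int = 10_000,
    low: float = 0.75,
    high: float = 1.25,
) -> pd.DataFrame:
    """Per-window depth normalised by the genome-wide median, with CNV flags.

    ``depth`` holds per-site records with columns ``chrom``, ``pos`` and
    ``depth``.  Each window's mean depth is divided by the genome-wide median
    of window means; windows with a ratio <= ``low`` or >= ``high`` are
    flagged as candidate copy-number variants, whose markers should be
    excluded from LOH analysis.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(depth) == 0:
        raise ValueError("empty depth track")
    d = depth.copy()
    d["win"] = (d["pos"] - 1) // window
    g = d.groupby(["chrom", "win"], sort=True)["depth"].mean().reset_index()
    median = float(g["depth"].median())
    if median <= 0:
        raise ValueError("non-positive median depth")
    g["start"] = g["win"] * window + 1
    g["end"] = (g["win"] + 1) * window
    g["ratio"] = g["depth"] / median
    g["flagged"] = (g["ratio"] <= low) | (g["ratio"] >= high)
    return g[["chrom", "start", "end", "depth", "ratio", "flagged"]].rename(
        columns={"depth": "mean_depth"}
    )


def cnv_marker_mask(windows: pd.DataFrame, marker_map: MarkerMap) -> np.ndarray:
    """Boolean mask of markers falling inside flagged coverage windows."""
    mask = np.zeros(marker_map.n_markers, dtype=bool)
    flagged = windows[windows["flagged"]]
    for chrom, sub in flagged.groupby("chrom"):
        try:
            sl = marker_map.chrom_slice(str(chrom))
        except KeyError:
            continue
        pos = marker_map.pos[sl]
        for r in sub.itertuples():
            mask[sl.start : sl.stop][(pos >= r.start) & (pos <= r.end)] = True
    return mask


# ------------------------------------------------------------------ matrix I/O
def genotypes_to_frame(
    marker_map: MarkerMap, calls_by_strain: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Markers x strains genotype matrix with string labels (P1/P2/HET/NA)."""
    markers, _ = marker_map.to_frames()
    out = markers[["chrom", "pos"]].copy()
    for strain, calls in calls_by_strain.items():
        if len(calls) != marker_map.n_markers:
            raise ValueError(f"{strain}: genotype vector length mismatch")
        out[strain] = [GENOTYPE_LABELS[int(c)] for c in calls]
    return out


def frame_to_genotypes(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Inverse of :func:`genotypes_to_frame` (ignores chrom/pos columns)."""
    out = {}
    for col in frame.columns:
        if col in ("chrom", "pos"):
            continue
        out[col] = frame[col].map(LABEL_TO_CODE).to_numpy(dtype=np.int8)
    return out


def write_genotypes(
    path: str | Path, marker_map: MarkerMap, calls_by_strain: dict[str, np.ndarray]
) -> None:
    genotypes_to_frame(marker_map, calls_by_strain).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> dict[str, np.ndarray]:
    return frame_to_genotypes(pd.read_csv(path, sep="\t"))
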