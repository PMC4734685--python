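"""LOH tract assembly and segregation-pattern classification.

A mother-daughter RTG pair carries the four chromatids of a single meiotic
cell, two per strain, so the paired diploid genotypes provide tetrad-like
segregation information at every marker: 2:2 (both heterozygous, or
homozygous with opposite genotypes), 3:1 (heterozygous in one strain,
homozygous in the other) or 4:0 (same homozygous genotype in both — excluded
from LOH analysis as a likely premeiotic conversion).

Tracts are assembled in two steps.  First the 3:1 markers are set aside and
contiguous 2:2-homozygous markers of the same orientation are grouped into
reciprocal LOH (rLOH) tracts; then all markers are regrouped and maximal
runs of 3:1 markers of the same genotype become non-reciprocal LOH (nrLOH)
tracts.  Each tract is labelled terminal (contains the arm's distal-most
genotyped marker) or interstitial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import GENOTYPE_LABELS, HET, HOM_P1, HOM_P2, NO_CALL
from .markers import IN_CENTROMERE, MarkerMap

# Segregation pattern codes.
PAT_NA = np.int8(-1)
TWO_TWO_HET = np.int8(0)
TWO_TWO_HOM = np.int8(1)
THREE_ONE = np.int8(2)
FOUR_ZERO = np.int8(3)

PATTERN_LABELS = {
    int(PAT_NA): "NA",
    int(TWO_TWO_HET): "2:2_het",
    int(TWO_TWO_HOM): "2:2_hom",
    int(THREE_ONE): "3:1",
    int(FOUR_ZERO): "4:0",
}

TERMINAL = "terminal"
INTERSTITIAL = "interstitial"


def classify_segregation_vectors(mother: np.ndarray, daughter: np.ndarray) -> np.ndarray:
    """Per-marker segregation pattern of an aligned mother/daughter pair."""
    mother = np.asarray(mother, dtype=np.int8)
    daughter = np.asarray(daughter, dtype=np.int8)
    if mother.shape != daughter.shape:
        raise ValueError("mother and daughter vectors have mismatched lengths")
    out = np.full(mother.shape, PAT_NA, dtype=np.int8)
    ok = (mother != NO_CALL) & (daughter != NO_CALL)
    m_het = mother == HET
    d_het = daughter == HET
    out[ok & m_het & d_het] = TWO_TWO_HET
    out[ok & ~m_het & ~d_het & (mother != daughter)] = TWO_TWO_HOM
    out[ok & ~m_het & ~d_het & (mother == daughter)] = FOUR_ZERO
    out[ok & (m_het ^ d_het)] = THREE_ONE
    return out


def classify_segregation(mother_call: int, daughter_call: int) -> int:
    """Segregation pattern for a single marker."""
    return int(
        classify_segregation_vectors(np.array([mother_call]), np.array([daughter_call]))[0]
    )


@dataclass
class LohTract:
    """A maximal run of markers sharing one LOH segregation pattern.

    ``start_idx``/``end_idx`` are inclusive global marker indices of the
    outermost member markers; ``n_markers`` counts member markers only
    (markers of other patterns may be interleaved in an rLOH span).
    """

    chrom: str
    start_idx: int
    end_idx: int
    start_pos: int
    end_pos: int
    n_markers: int
    reciprocity: str  # "rLOH" | "nrLOH"
    mother_genotype: int
    daughter_genotype: int
    arm: int | None = None
    position: str | None = None  # terminal | interstitial | None
    spans_centromere: bool = False

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def hom_strain(self) -> str | None:
        """For nrLOH tracts, which strain is homozygous."""
        if self.reciprocity != "nrLOH":
            return None
        return "daughter" if self.mother_genotype == HET else "mother"


def _pattern_runs(pat_values: np.ndarray, keys: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of equal keys within a condensed sequence."""
    if pat_values.size == 0:
        return []
    change = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [pat_values.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def assemble_pair_tracts(
    mother: np.ndarray,
    daughter: np.ndarray,
    marker_map: MarkerMap,
    min_markers: int = 1,
    exclude: np.ndarray | None = None,
) -> tuple[list[LohTract], dict]:
    """Two-step LOH tract assembly for a mother-daughter pair.

    Markers in ``exclude`` (e.g. inside candidate CNV windows) and 4:0
    markers are removed before assembly.  Returns the tract list (rLOH then
    nrLOH, ordered by position within each class) and an ``info`` dict with
    the pattern array, the retained-marker mask and exclusion counts.
    """
    mother = np.asarray(mother, dtype=np.int8)
    daughter = np.asarray(daughter, dtype=np.int8)
    if mother.size != marker_map.n_markers:
        raise ValueError("genotype vectors do not match the marker map")
    pat = classify_segregation_vectors(mother, daughter)
    retained = pat != PAT_NA
    n_four_zero = int(np.count_nonzero(pat == FOUR_ZERO))
    retained &= pat != FOUR_ZERO
    if exclude is not None:
        retained &= ~np.asarray(exclude, dtype=bool)

    tracts: list[LohTract] = []
    for ci in range(len(marker_map.chromosomes)):
        sl = marker_map.chrom_slice(ci)
        idx = np.arange(sl.start, sl.stop)
        keep = retained[sl]
        idx = idx[keep]
        if idx.size == 0:
            continue
        p = pat[idx]
        name = marker_map.chrom_name(ci)

        # Step 1: set 3:1 markers aside, group 2:2-hom runs of one orientation.
        two_two = idx[p != THREE_ONE]
        if two_two.size:
            # key: -1 for 2:2-het, else mother's homozygous genotype
            key = np.where(pat[two_two] == TWO_TWO_HOM, mother[two_two], -1)
            for a, b in _pattern_runs(pat[two_two], key):
                if key[a] == -1:
                    continue
                members = two_two[a:b]
                if members.size < min_markers:
                    continue
                tracts.append(
                    _make_tract(marker_map, name, members, "rLOH", mother, daughter)
                )

        # Step 2: all markers together, maximal 3:1 runs of one genotype.
        key2 = np.where(p == THREE_ONE, mother[idx] * 4 + daughter[idx] + 16, p)
        for a, b in _pattern_runs(p, key2):
            if p[a] != THREE_ONE:
                continue
            members = idx[a:b]
            if members.size < min_markers:
                continue
            tracts.append(
                _make_tract(marker_map, name, members, "nrLOH", mother, daughter)
            )

    for t in tracts:
        classify_tract_position(t, marker_map, retained)
    tracts.sort(key=lambda t: (t.reciprocity != "rLOH", t.chrom, t.start_pos))
    info = {
        "patterns": pat,
        "retained": retained,
        "n_four_zero": n_four_zero,
        "n_na": int(np.count_nonzero(pat == PAT_NA)),
    }
    return tracts, info


def _make_tract(
    marker_map: MarkerMap,
    chrom: str,
    members: np.ndarray,
    reciprocity: str,
    mother: np.ndarray,
    daughter: np.ndarray,
) -> LohTract:
    first, last = int(members[0]), int(members[-1])
    return LohTract(
        chrom=chrom,
        start_idx=first,
        end_idx=last,
        start_pos=int(marker_map.pos[first]),
        end_pos=int(marker_map.pos[last]),
        n_markers=int(members.size),
        reciprocity=reciprocity,
        mother_genotype=int(mother[first]),
        daughter_genotype=int(daughter[first]),
    )


def classify_tract_position(
    tract: LohTract, marker_map: MarkerMap, retained: np.ndarray | None = None
) -> str | None:
    """Label a tract terminal or interstitial on its chromosome arm.

    A tract is terminal iff it contains the arm's distal-most retained
    marker.  Tracts whose ends fall on different arms (spanning the
    centromere) are flagged and left unlabelled for review; markers inside
    the centromere interval belong to no arm.
    """
    arm_start = int(marker_map.arm[tract.start_idx])
    arm_end = int(marker_map.arm[tract.end_idx])
    if arm_start != arm_end or arm_start == IN_CENTROMERE:
        tract.spans_centromere = True
        tract.arm = None
        tract.position = None
        return None
    tract.arm = arm_start
    ci = int(marker_map.chrom_idx[tract.start_idx])
    terminal_marker = marker_map.arm_terminal_marker(ci, arm_start, retained)
    is_terminal = terminal_marker is not None and (
        tract.start_idx <= terminal_marker <= tract.end_idx
    )
    tract.position = TERMINAL if is_terminal else INTERSTITIAL
    return tract.position


# ------------------------------------------------------------------- summaries
def summarize_loh(calls_by_strain: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-strain homozygosity summary over called markers."""
    if not calls_by_strain:
        raise ValueError("no genotype vectors supplied")
    rows = []
    for strain, calls in calls_by_strain.items():
        calls = np.asarray(calls, dtype=np.int8)
        called = calls != NO_CALL
        n_called = int(called.sum())
        n_p1 = int(np.count_nonzero(calls == HOM_P1))
        n_p2 = int(np.count_nonzero(calls == HOM_P2))
        rows.append(
            {
                "strain": strain,
                "n_markers": int(calls.size),
                "n_called": n_called,
                "frac_hom": (n_p1 + n_p2) / n_called if n_called else np.nan,
                "frac_hom_p1": n_p1 / n_called if n_called else np.nan,
                "frac_hom_p2": n_p2 / n_called if n_called else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_tracts(tracts: list[LohTract]) -> pd.DataFrame:
    """Tract count and mean length per (reciprocity, position) class."""
    if not tracts:
        return pd.DataFrame(
            columns=["reciprocity", "position", "n_tracts", "mean_span_bp", "total_markers"]
        )
    rows = [
        {
            "reciprocity": t.reciprocity,
            "position": t.position or "unassigned",
            "span_bp": t.span_bp,
            "n_markers": t.n_markers,
        }
        for t in tracts
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["reciprocity", "position"], sort=True)
        .agg(n_tracts=("span_bp", "size"), mean_span_bp=("span_bp", "mean"),
             total_markers=("n_markers", "sum"))
        .reset_index()
    )
    return out


def tracts_to_frame(tracts: list[LohTract]) -> pd.DataFrame:
    rows = []
    for t in tracts:
        rows.append(
            {
                "chrom": t.chrom,
                "start_pos": t.start_pos,
                "end_pos": t.end_pos,
                "n_markers": t.n_markers,
                "reciprocity": t.reciprocity,
                "position": t.position or "unassigned",
                "mother_genotype": GENOTYPE_LABELS[t.mother_genotype],
                "daughter_genotype": GENOTYPE_LABELS[t.daughter_genotype],
                "spans_centromere": t.spans_centromere,
            }
        )
    return pd.DataFrame(rows)


def tracts_to_bed(tracts: list[LohTract]) -> pd.DataFrame:
    """BED representation (0-based half-open) of a tract list.

    The name field encodes reciprocity, position and the mother/daughter
    genotypes, e.g. ``rLOH|terminal|P1/P2``.
    """
    rows = []
    for t in tracts:
        name = "|".join(
            [
                t.reciprocity,
                t.position or "unassigned",
                f"{GENOTYPE_LABELS[t.mother_genotype]}/{GENOTYPE_LABELS[t.daughter_genotype]}",
            ]
        )
        rows.append(
            {"chrom": t.chrom, "start": t.start_pos - 1, "end": t.end_pos, "name": name}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


__all__ = [
    "PAT_NA",
    "TWO_TWO_HET",
    "TWO_TWO_HOM",
    "THREE_ONE",
    "FOUR_ZERO",
    "PATTERN_LABELS",
    "TERMINAL",
    "INTERSTITIAL",
    "LohTract",
    "classify_segregation",
    "classify_segregation_vectors",
    "assemble_pair_tracts",
    "classify_tract_position",
    "summarize_loh",
    "summarize_tracts",
    "tracts_to_frame",
    "tracts_to_bed",
]
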