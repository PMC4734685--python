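"""Recombination event calling from paired RTG genotypes.

Crossovers (CO) are read off the boundaries of reciprocal LOH tracts — a
terminal rLOH reflects one CO, an interstitial rLOH two.  Non-reciprocal
tracts are classified by their position relative to rLOH tracts: a gene
conversion adjacent to an rLOH boundary is a CO-associated GC, a
non-reciprocal tract inside heterozygous context (or inside an rLOH span) is
a non-crossover (NCO), and one reaching the end of a chromosome arm is a
terminal NCO.  Crossovers whose two recombinant chromatids co-segregated
into the same cell leave no rLOH ("masked" COs); they are revealed by
sporulating the RTG diploid and genotyping the four spores of a tetrad,
where a masked CO appears as two pairs of reciprocal recombinant molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_P1, HOM_P2, NO_CALL
from .loh import (
    INTERSTITIAL,
    LohTract,
    TERMINAL,
    assemble_pair_tracts,
)
from .markers import LEFT_ARM, MarkerMap, RIGHT_ARM

CO = "CO"
CO_GC = "CO_GC"
NCO = "NCO"
TERMINAL_NCO = "TERMINAL_NCO"

_KIND_RANK = {CO_GC: 3, CO: 2, TERMINAL_NCO: 1, NCO: 1}


@dataclass
class RecombEvent:
    """One inferred recombination event.

    ``start_pos``/``end_pos`` bound the breakpoint interval (1-based,
    inclusive marker positions of the flanking markers); for conversion
    events they bound the converted tract.  ``breakpoint_idx`` holds, for CO
    and CO-GC events, the pair of marker indices flanking the inferred
    exchange point.
    """

    kind: str
    chrom: str
    start_pos: int
    end_pos: int
    start_idx: int
    end_idx: int
    tracts: tuple[LohTract, ...] = ()
    source: str = "pair_analysis"
    arm: int | None = None
    breakpoint_idx: tuple[int, int] | None = None


def build_pseudotetrad(
    mother: np.ndarray, daughter: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a diploid pair into four chromatid haplotypes.

    Returns a ``(4, n_kept)`` array of parental contents (0 = P1, 1 = P2;
    chromatids 0-1 from the mother, 2-3 from the daughter) and the boolean
    mask of markers kept (called in both strains).  At heterozygous markers
    the first chromatid of each strain carries P1 and the second P2; at
    homozygous markers both chromatids carry the homozygous parent.
    """
    mother = np.asarray(mother, dtype=np.int8)
    daughter = np.asarray(daughter, dtype=np.int8)
    if mother.shape != daughter.shape:
        raise ValueError("mother and daughter vectors have mismatched lengths")
    kept = (mother != NO_CALL) & (daughter != NO_CALL)
    m = mother[kept]
    d = daughter[kept]

    def split(g: np.ndarray) -> np.ndarray:
        first = np.where(g == HET, 0, g // 2).astype(np.int8)
        second = np.where(g == HET, 1, g // 2).astype(np.int8)
        return np.vstack([first, second])

    return np.vstack([split(m), split(d)]), kept


def merge_chromatids(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Diploid genotype vector from two chromatid content vectors."""
    return (np.asarray(first, dtype=np.int8) + np.asarray(second, dtype=np.int8)).astype(
        np.int8
    )


def count_cos(tracts: list[LohTract]) -> int:
    """CO count implied by rLOH tracts: one per terminal, two per interstitial."""
    n = 0
    for t in tracts:
        if t.reciprocity != "rLOH" or t.position is None:
            continue
        n += 1 if t.position == TERMINAL else 2
    return n


def _nearest_retained(
    idx: int, direction: int, retained: np.ndarray, sl: slice
) -> int | None:
    """Nearest retained marker index strictly beyond ``idx`` within a chromosome."""
    j = idx + direction
    while sl.start <= j < sl.stop:
        if retained[j]:
            return j
        j += direction
    return None


def classify_nrloh(
    tract: LohTract,
    rloh_tracts: list[LohTract],
    marker_map: MarkerMap,
    retained: np.ndarray,
) -> str:
    """Classify one non-reciprocal tract as CO_GC, NCO or TERMINAL_NCO.

    The tract is a CO-associated GC iff its immediate retained neighbour
    marker (on either side) lies inside an rLOH tract span — i.e. no
    differently-genotyped marker intervenes between the conversion tract and
    the rLOH boundary.  A tract lying fully inside an rLOH span is an NCO,
    as is a tract inside heterozygous context; a tract containing the arm's
    distal-most retained marker (and not bordering an rLOH) is terminal.
    """
    same_chrom = [r for r in rloh_tracts if r.reciprocity == "rLOH" and r.chrom == tract.chrom]
    for r in same_chrom:
        if max(r.start_idx, tract.start_idx) <= min(r.end_idx, tract.end_idx):
            if r.start_idx <= tract.start_idx and tract.end_idx <= r.end_idx:
                return NCO  # conversion inside a reciprocal LOH region
            raise ValueError("overlapping rLOH/nrLOH tracts that are not nested")
    ci = int(marker_map.chrom_idx[tract.start_idx])
    sl = marker_map.chrom_slice(ci)
    for direction in (-1, 1):
        edge = tract.start_idx if direction == -1 else tract.end_idx
        nb = _nearest_retained(edge, direction, retained, sl)
        if nb is None:
            continue
        for r in same_chrom:
            if r.start_idx <= nb <= r.end_idx:
                return CO_GC
    if tract.arm is not None:
        terminal_marker = marker_map.arm_terminal_marker(ci, tract.arm, retained)
        if terminal_marker is not None and tract.start_idx <= terminal_marker <= tract.end_idx:
            return TERMINAL_NCO
    return NCO


def call_pair_events(
    mother: np.ndarray,
    daughter: np.ndarray,
    marker_map: MarkerMap,
    min_markers: int = 1,
    exclude: np.ndarray | None = None,
) -> tuple[list[RecombEvent], list[LohTract], dict]:
    """Full event calling for one mother-daughter pair.

    Assembles LOH tracts, emits one CO event per rLOH boundary (terminal
    tracts have a single proximal boundary), classifies every nrLOH tract
    and upgrades CO events to CO-GC when a conversion tract abuts their
    boundary.  Returns (events, tracts, info).
    """
    tracts, info = assemble_pair_tracts(
        mother, daughter, marker_map, min_markers=min_markers, exclude=exclude
    )
    retained = info["retained"]
    rlohs = [t for t in tracts if t.reciprocity == "rLOH"]
    nrlohs = [t for t in tracts if t.reciprocity == "nrLOH"]

    events: list[RecombEvent] = []
    co_by_boundary: dict[tuple[int, int], RecombEvent] = {}
    for t in rlohs:
        if t.position is None:
            continue
        ci = int(marker_map.chrom_idx[t.start_idx])
        sl = marker_map.chrom_slice(ci)
        boundaries = []
        # proximal/distal edges in index space depend on the arm orientation
        edges = [(t.start_idx, -1), (t.end_idx, +1)]
        for edge, direction in edges:
            nb = _nearest_retained(edge, direction, retained, sl)
            if nb is None:
                continue  # tract reaches the arm end: no boundary on that side
            boundaries.append((min(edge, nb), max(edge, nb)))
        for lo, hi in boundaries:
            ev = RecombEvent(
                kind=CO,
                chrom=t.chrom,
                start_pos=int(marker_map.pos[lo]),
                end_pos=int(marker_map.pos[hi]),
                start_idx=lo,
                end_idx=hi,
                tracts=(t,),
                arm=t.arm,
                breakpoint_idx=(lo, hi),
            )
            events.append(ev)
            co_by_boundary[(lo, hi)] = ev

    for t in nrlohs:
        kind = classify_nrloh(t, rlohs, marker_map, retained)
        if kind == CO_GC:
            ev = _attach_gc(t, co_by_boundary, marker_map, retained)
            if ev is not None:
                continue
            # conversion abuts an rLOH edge that has no boundary event
            # (e.g. the tract reaches the arm end); emit a standalone event
        events.append(
            RecombEvent(
                kind=kind,
                chrom=t.chrom,
                start_pos=t.start_pos,
                end_pos=t.end_pos,
                start_idx=t.start_idx,
                end_idx=t.end_idx,
                tracts=(t,),
                arm=t.arm,
            )
        )

    events.sort(key=lambda e: (e.chrom, e.start_pos, e.end_pos))
    info["n_co"] = count_cos(rlohs)
    return events, tracts, info


def _attach_gc(
    tract: LohTract,
    co_by_boundary: dict[tuple[int, int], RecombEvent],
    marker_map: MarkerMap,
    retained: np.ndarray,
) -> RecombEvent | None:
    """Upgrade the CO event whose boundary interval abuts a conversion tract."""
    ci = int(marker_map.chrom_idx[tract.start_idx])
    sl = marker_map.chrom_slice(ci)
    for direction in (-1, 1):
        edge = tract.start_idx if direction == -1 else tract.end_idx
        nb = _nearest_retained(edge, direction, retained, sl)
        if nb is None:
            continue
        for (lo, hi), ev in co_by_boundary.items():
            # the CO boundary interval must contain or abut the tract edge
            if lo <= edge <= hi or lo <= nb <= hi or nb in (lo, hi):
                if ev.chrom != tract.chrom:
                    continue
                ev.kind = CO_GC
                ev.tracts = ev.tracts + (tract,)
                ev.start_idx = min(ev.start_idx, tract.start_idx)
                ev.end_idx = max(ev.end_idx, tract.end_idx)
                ev.start_pos = int(marker_map.pos[ev.start_idx])
                ev.end_pos = int(marker_map.pos[ev.end_idx])
                # implied exchange point: the gap between the conversion tract
                # and the heterozygous context when the GC sits on the
                # homozygous side of the boundary
                return ev
    return None


def merge_events(
    events: list[RecombEvent], max_gap: int = 5000
) -> tuple[list[RecombEvent], list[dict]]:
    """Merge closely spaced events and refine their classification.

    Events on the same chromosome whose breakpoint intervals lie within
    ``max_gap`` bp are merged.  The merged kind follows the precedence
    CO_GC > CO > NCO, with the refinement that a CO merged with a nearby
    conversion event becomes a CO-GC.  Every merge is logged.
    """
    if not events:
        return [], []
    ordered = sorted(events, key=lambda e: (e.chrom, e.start_pos, e.end_pos))
    merged: list[RecombEvent] = []
    log: list[dict] = []
    cluster = [ordered[0]]
    for ev in ordered[1:]:
        last = cluster[-1]
        if ev.chrom == last.chrom and ev.start_pos - max(c.end_pos for c in cluster) <= max_gap:
            cluster.append(ev)
        else:
            merged.append(_collapse(cluster, log))
            cluster = [ev]
    merged.append(_collapse(cluster, log))
    return merged, log


def _collapse(cluster: list[RecombEvent], log: list[dict]) -> RecombEvent:
    if len(cluster) == 1:
        return cluster[0]
    kinds = [e.kind for e in cluster]
    has_co = any(k in (CO, CO_GC) for k in kinds)
    has_conv = any(k in (CO_GC, NCO, TERMINAL_NCO) for k in kinds)
    if has_co and has_conv:
        kind = CO_GC
    elif has_co:
        kind = CO
    else:
        kind = TERMINAL_NCO if TERMINAL_NCO in kinds else NCO
    out = RecombEvent(
        kind=kind,
        chrom=cluster[0].chrom,
        start_pos=min(e.start_pos for e in cluster),
        end_pos=max(e.end_pos for e in cluster),
        start_idx=min(e.start_idx for e in cluster),
        end_idx=max(e.end_idx for e in cluster),
        tracts=tuple(t for e in cluster for t in e.tracts),
        source=cluster[0].source,
        arm=cluster[0].arm,
    )
    log.append(
        {
            "chrom": out.chrom,
            "start_pos": out.start_pos,
            "end_pos": out.end_pos,
            "merged_kinds": kinds,
            "result_kind": kind,
            "n_events": len(cluster),
        }
    )
    return out


def events_to_frame(events: list[RecombEvent]) -> pd.DataFrame:
    rows = [
        {
            "kind": e.kind,
            "chrom": e.chrom,
            "start_pos": e.start_pos,
            "end_pos": e.end_pos,
            "n_tracts": len(e.tracts),
            "source": e.source,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["kind", "chrom", "start_pos", "end_pos", "n_tracts", "source"]
    )


# --------------------------------------------------------- masked-CO revealing
@dataclass
class MaskedCoReport:
    """Outcome of comparing an RTG parent with its sporulated tetrad."""

    masked: list[RecombEvent]
    n_sporulation_cos: int
    n_sporulation_conversions: int
    frac_hom_4_0: float
    frac_het_mendelian: float
    flagged: list[dict] = field(default_factory=list)


def reveal_masked_cos(
    mother: np.ndarray,
    daughter: np.ndarray,
    spores: np.ndarray,
    marker_map: MarkerMap,
    sporulated: str = "mother",
    max_gap_bp: int = 10_000,
) -> MaskedCoReport:
    """Reveal masked crossovers from the four spores of a sporulated RTG.

    The mother-daughter pair is analysed first; only crossovers that
    produced no reciprocal LOH in the pair are candidates.  Between
    consecutive markers heterozygous in the sporulated parent, each spore's
    genotype switch marks a recombination breakpoint.  A gap in which *all
    four* spores switch means both parental haplotypes were recombinant at
    that point — a crossover already present in the parent that produced no
    rLOH (a masked CO, appearing as two pairs of reciprocal recombinant
    spores).  This holds with or without an adjacent conversion tract: the
    parent is homozygous over its own CO-associated GC tract, so those
    markers drop out of the heterozygous frame and both haplotype
    breakpoints collapse into one gap.  A gap with exactly two switching
    spores is a crossover that arose during sporulation (which involves only
    two of the four chromatids); single switches bound sporulation
    conversion tracts; three switches are flagged.  Gaps spanning a detected
    rLOH tract of the pair (whose crossovers were already counted) or wider
    than ``max_gap_bp`` carry no new information and are skipped.

    Mendelian QC: markers homozygous in the parent must segregate 4:0 and
    heterozygous markers 2:2 or 3:1; the observed fractions are reported.
    """
    mother = np.asarray(mother, dtype=np.int8)
    daughter = np.asarray(daughter, dtype=np.int8)
    parent = mother if sporulated == "mother" else daughter
    spores = np.asarray(spores, dtype=np.int8)
    if spores.shape != (4, parent.size):
        raise ValueError("expected exactly four spore vectors aligned to the parent")
    pair_tracts, _ = assemble_pair_tracts(mother, daughter, marker_map)
    in_rloh = np.zeros(parent.size, dtype=bool)
    for t in pair_tracts:
        if t.reciprocity == "rLOH":
            in_rloh[t.start_idx : t.end_idx + 1] = True
    retained = (parent != NO_CALL) & np.all(spores != NO_CALL, axis=0)

    hom = retained & ((parent == HOM_P1) | (parent == HOM_P2))
    n_hom = int(hom.sum())
    frac_4_0 = (
        float(np.all(spores[:, hom] == parent[hom], axis=0).mean()) if n_hom else np.nan
    )
    het = retained & (parent == HET)
    n_het = int(het.sum())
    if n_het:
        n_p2 = (spores[:, het] // 2).sum(axis=0)
        frac_mend = float(np.isin(n_p2, (1, 2, 3)).mean())
    else:
        frac_mend = np.nan

    content = (spores // 2).astype(np.int8)
    masked: list[RecombEvent] = []
    n_spo_co = 0
    n_conv_boundaries = 0
    flagged: list[dict] = []
    for ci in range(len(marker_map.chromosomes)):
        sl = marker_map.chrom_slice(ci)
        name = marker_map.chrom_name(ci)
        idx = np.arange(sl.start, sl.stop)
        het_idx = idx[het[sl]]
        if het_idx.size < 2:
            continue
        sw = content[:, het_idx[1:]] != content[:, het_idx[:-1]]  # (4, n_gaps)
        gap_bp = marker_map.pos[het_idx[1:]] - marker_map.pos[het_idx[:-1]]
        for j in np.flatnonzero(sw.any(axis=0)):
            lo_idx, hi_idx = int(het_idx[j]), int(het_idx[j + 1])
            n_sw = int(sw[:, j].sum())
            if gap_bp[j] > max_gap_bp or np.any(in_rloh[lo_idx : hi_idx + 1]):
                flagged.append(
                    {
                        "chrom": name,
                        "start_pos": int(marker_map.pos[lo_idx]),
                        "end_pos": int(marker_map.pos[hi_idx]),
                        "n_switching_spores": n_sw,
                        "reason": "spans_detected_rloh"
                        if np.any(in_rloh[lo_idx : hi_idx + 1])
                        else "gap_too_wide",
                    }
                )
                continue
            if n_sw == 4:
                masked.append(
                    RecombEvent(
                        kind=CO,
                        chrom=name,
                        start_pos=int(marker_map.pos[lo_idx]),
                        end_pos=int(marker_map.pos[hi_idx]),
                        start_idx=lo_idx,
                        end_idx=hi_idx,
                        source="tetrad_reveal",
                    )
                )
            elif n_sw == 2:
                n_spo_co += 1
            elif n_sw in (1, 3):
                n_conv_boundaries += 1
                if n_sw == 3:
                    flagged.append(
                        {
                            "chrom": name,
                            "start_pos": int(marker_map.pos[lo_idx]),
                            "end_pos": int(marker_map.pos[hi_idx]),
                            "n_switching_spores": 3,
                            "reason": "odd_switch_count",
                        }
                    )
    return MaskedCoReport(
        masked=masked,
        n_sporulation_cos=n_spo_co,
        n_sporulation_conversions=n_conv_boundaries,
        frac_hom_4_0=frac_4_0,
        frac_het_mendelian=frac_mend,
        flagged=flagged,
    )
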