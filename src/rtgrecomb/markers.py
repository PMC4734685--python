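"""Hybrid marker maps.

A :class:`MarkerMap` holds the ordered SNP markers that distinguish the two
parental haplotypes of a hybrid diploid (P1, the reference-like parent, and
P2, the alternate parent), together with per-chromosome metadata (length and
centromere interval).  Marker positions are 1-based; markers are stored in a
single flat order, grouped by chromosome and strictly increasing in position
within each chromosome, so that per-strain genotype vectors can be plain
aligned arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Arm codes returned by :attr:`MarkerMap.arm`.
LEFT_ARM = 0
RIGHT_ARM = 1
IN_CENTROMERE = -1


@dataclass(frozen=True)
class Chromosome:
    """Per-chromosome metadata: physical length and centromere interval (bp, closed)."""

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: non-positive length")
        if not (1 <= self.cen_start <= self.cen_end <= self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.cen_start}, {self.cen_end}] "
                f"outside [1, {self.length}]"
            )


class MarkerMap:
    """Ordered SNP markers over a set of chromosomes.

    Parameters
    ----------
    chromosomes:
        Chromosome metadata, in the order chromosomes appear in the marker
        arrays.
    chrom_idx:
        Per-marker index into ``chromosomes``; must be grouped and
        non-decreasing.
    pos:
        Per-marker 1-based position, strictly increasing within a chromosome.
    p1_allele, p2_allele:
        Optional nucleotide labels of the two parental haplotypes at each
        marker.
    """

    def __init__(
        self,
        chromosomes: list[Chromosome],
        chrom_idx: np.ndarray,
        pos: np.ndarray,
        p1_allele: np.ndarray | None = None,
        p2_allele: np.ndarray | None = None,
    ):
        self.chromosomes = list(chromosomes)
        self.chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        if self.chrom_idx.shape != self.pos.shape:
            raise ValueError("chrom_idx and pos must have the same length")
        self.p1_allele = None if p1_allele is None else np.asarray(p1_allele)
        self.p2_allele = None if p2_allele is None else np.asarray(p2_allele)
        self._validate()
        self._bounds = np.searchsorted(self.chrom_idx, np.arange(len(self.chromosomes) + 1))
        self.arm = self._compute_arms()

    # ------------------------------------------------------------------ basics
    def _validate(self) -> None:
        if np.any(np.diff(self.chrom_idx) < 0):
            raise ValueError("markers must be grouped by chromosome in order")
        n_chrom = len(self.chromosomes)
        if self.chrom_idx.size and not (
            0 <= self.chrom_idx.min() and self.chrom_idx.max() < n_chrom
        ):
            raise ValueError("chrom_idx out of range")
        for ci, chrom in enumerate(self.chromosomes):
            sl = np.flatnonzero(self.chrom_idx == ci)
            if sl.size == 0:
                continue
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"{chrom.name}: positions not strictly increasing")
            if p[0] < 1 or p[-1] > chrom.length:
                raise ValueError(f"{chrom.name}: marker position outside [1, length]")

    def _compute_arms(self) -> np.ndarray:
        arm = np.full(self.n_markers, IN_CENTROMERE, dtype=np.int8)
        for ci, chrom in enumerate(self.chromosomes):
            sl = self.chrom_slice(ci)
            p = self.pos[sl]
            a = np.full(p.size, IN_CENTROMERE, dtype=np.int8)
            a[p < chrom.cen_start] = LEFT_ARM
            a[p > chrom.cen_end] = RIGHT_ARM
            arm[sl] = a
        return arm

    @property
    def n_markers(self) -> int:
        return int(self.pos.size)

    def chrom_slice(self, chrom: int | str) -> slice:
        """Contiguous slice of marker indices for one chromosome."""
        ci = self.chrom_index(chrom)
        return slice(int(self._bounds[ci]), int(self._bounds[ci + 1]))

    def chrom_index(self, chrom: int | str) -> int:
        if isinstance(chrom, str):
            for i, c in enumerate(self.chromosomes):
                if c.name == chrom:
                    return i
            raise KeyError(chrom)
        return int(chrom)

    def chrom_name(self, ci: int) -> str:
        return self.chromosomes[ci].name

    def arm_markers(self, chrom: int | str, arm: int) -> np.ndarray:
        """Global marker indices of one arm, ordered proximal to distal.

        For the left arm the distal end is the chromosome start, so indices
        run from the centromere outward (descending position).
        """
        sl = self.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        idx = idx[self.arm[sl] == arm]
        if arm == LEFT_ARM:
            idx = idx[::-1]
        return idx

    def arm_terminal_marker(
        self, chrom: int | str, arm: int, retained: np.ndarray | None = None
    ) -> int | None:
        """Global index of the arm's distal-most (telomere-proximal) retained marker."""
        idx = self.arm_markers(chrom, arm)
        if retained is not None:
            idx = idx[retained[idx]]
        if idx.size == 0:
            return None
        return int(idx[-1])

    # --------------------------------------------------------------------- I/O
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        markers = pd.DataFrame(
            {
                "chrom": [self.chromosomes[i].name for i in self.chrom_idx],
                "pos": self.pos,
                "p1_allele": self.p1_allele if self.p1_allele is not None else "N",
                "p2_allele": self.p2_allele if self.p2_allele is not None else "N",
            }
        )
        chroms = pd.DataFrame(
            [
                {
                    "chrom": c.name,
                    "length": c.length,
                    "cen_start": c.cen_start,
                    "cen_end": c.cen_end,
                }
                for c in self.chromosomes
            ]
        )
        return markers, chroms

    @classmethod
    def from_frames(cls, markers: pd.DataFrame, chroms: pd.DataFrame) -> "MarkerMap":
        chromosomes = [
            Chromosome(str(r.chrom), int(r.length), int(r.cen_start), int(r.cen_end))
            for r in chroms.itertuples()
        ]
        name_to_idx = {c.name: i for i, c in enumerate(chromosomes)}
        chrom_idx = markers["chrom"].map(name_to_idx)
        if chrom_idx.isna().any():
            bad = markers.loc[chrom_idx.isna(), "chrom"].unique()
            raise ValueError(f"markers on unknown chromosome(s): {list(bad)}")
        return cls(
            chromosomes,
            chrom_idx.to_numpy(dtype=np.int32),
            markers["pos"].to_numpy(dtype=np.int64),
            markers["p1_allele"].to_numpy() if "p1_allele" in markers else None,
            markers["p2_allele"].to_numpy() if "p2_allele" in markers else None,
        )

    def write_tsv(self, markers_path: str | Path, chroms_path: str | Path) -> None:
        markers, chroms = self.to_frames()
        markers.to_csv(markers_path, sep="\t", index=False)
        chroms.to_csv(chroms_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, markers_path: str | Path, chroms_path: str | Path) -> "MarkerMap":
        return cls.from_frames(
            pd.read_csv(markers_path, sep="\t"), pd.read_csv(chroms_path, sep="\t")
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"MarkerMap({len(self.chromosomes)} chromosomes, {self.n_markers} markers)"
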