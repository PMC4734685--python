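"""Single-marker genotype-phenotype linkage with a permutation threshold.

RTG diploid cohorts are fully genotyped at dense markers, so a single-marker
scan suffices: at each marker the phenotype is modelled as normal with a
separate mean per diploid genotype class (HOM_P1 / HET / HOM_P2), and the
LOD score is the log10 likelihood ratio against a single common mean,
``LOD = (n/2) * log10(RSS0 / RSS1)``.  Binary traits are handled by the same
normal machinery (equivalent to comparing class frequencies for ranking
purposes); an optional binary collapse merges the homozygous classes carrying
the recessive allele.  Genome-wide significance uses the empirical
(1 - alpha) quantile of the maximal LOD over permutations of the phenotype
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_P1, HOM_P2, NO_CALL
from .markers import MarkerMap

_EPS_FRACTION = 1e-12


@dataclass
class LodScan:
    """Per-marker LOD values; NaN marks skipped (monomorphic or uncallable) markers."""

    lod: np.ndarray
    n_scanned: int
    threshold: float | None = None

    @property
    def max_lod(self) -> float:
        return float(np.nanmax(self.lod)) if self.n_scanned else 0.0


def _lod_matrix(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """LOD for every (marker, phenotype column) pair; NaN where not scannable.

    ``genotypes``: (n_markers, n_strains) int8; ``phenotypes``:
    (n_strains, n_pheno) float.  Markers with fewer than two genotype
    classes among called strains are NaN.  A perfect within-class fit is
    capped by flooring the residual sum of squares at a small fraction of
    the total.
    """
    G = np.asarray(genotypes)
    Y = np.asarray(phenotypes, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    called = (G != NO_CALL).astype(np.float64)  # (M, N)
    n = called.sum(axis=1)  # markers may have missing calls
    sy = called @ Y  # (M, P)
    sy2 = called @ (Y**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss0 = sy2 - sy**2 / n[:, None]
        rss1 = sy2.copy()
        n_classes = np.zeros(G.shape[0], dtype=np.int32)
        for cls in (HOM_P1, HET, HOM_P2):
            mask = (G == cls).astype(np.float64)
            n_c = mask.sum(axis=1)
            n_classes += (n_c > 0).astype(np.int32)
            s_c = mask @ Y
            contrib = np.where(n_c[:, None] > 0, s_c**2 / np.maximum(n_c, 1)[:, None], 0.0)
            rss1 -= contrib
        rss1 = np.maximum(rss1, _EPS_FRACTION * np.maximum(rss0, _EPS_FRACTION))
        lod = (n[:, None] / 2.0) * np.log10(rss0 / rss1)
    lod[~np.isfinite(lod)] = np.nan
    lod[rss0.max(axis=1) <= 0, :] = np.nan  # constant phenotype among called strains
    lod[n_classes < 2, :] = np.nan  # monomorphic markers are skipped
    return lod


def _prepare(genotypes: np.ndarray, phenotype: np.ndarray, binary_collapse: bool):
    G = np.asarray(genotypes, dtype=np.int8)
    y = np.asarray(phenotype, dtype=np.float64)
    if G.shape[1] != y.size:
        raise ValueError("genotype matrix and trait table cover different strains")
    if binary_collapse:
        # pool the two homozygous classes: homozygosity vs heterozygosity
        G = G.copy()
        G[G == HOM_P2] = HOM_P1
    return G, y


def lod_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    binary_collapse: bool = False,
) -> LodScan:
    """Single-marker LOD scan of a genotype matrix against one trait.

    ``genotypes`` is (n_markers, n_strains) with diploid codes; monomorphic
    markers are skipped (NaN).  With ``binary_collapse`` the two homozygous
    classes are pooled, testing homozygosity itself against the trait.
    """
    G, y = _prepare(genotypes, phenotype, binary_collapse)
    if np.ptp(y) == 0:
        import warnings

        warnings.warn("phenotype is constant; all LOD scores are zero", stacklevel=2)
        lod = np.zeros(G.shape[0])
        lod[:] = np.nan
        return LodScan(lod=lod, n_scanned=0)
    lod = _lod_matrix(G, y[:, None])[:, 0]
    return LodScan(lod=lod, n_scanned=int(np.isfinite(lod).sum()))


def permutation_threshold(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    binary_collapse: bool = False,
    batch: int = 250,
) -> float:
    """Genome-wide LOD significance threshold by phenotype permutation.

    The threshold is the empirical (1 - alpha) quantile — conservative
    ceiling order statistic — of the maximal LOD over ``n_perm`` random
    permutations of the phenotype labels.  Reproducible for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alpha >= 1.0:
        return 0.0
    G, y = _prepare(genotypes, phenotype, binary_collapse)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; permutation threshold undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        Y = np.empty((y.size, b))
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        lod = _lod_matrix(G, Y)
        maxima[done : done + b] = np.nanmax(lod, axis=0)
        done += b
    maxima.sort()
    rank = ceil((1.0 - alpha) * n_perm)  # 1-based conservative order statistic
    return float(maxima[min(rank, n_perm) - 1])


def significant_intervals(
    scan: LodScan, threshold: float, marker_map: MarkerMap
) -> pd.DataFrame:
    """Contiguous marker runs with LOD above the threshold, as bp intervals."""
    rows = []
    above = np.nan_to_num(scan.lod, nan=-np.inf) > threshold
    for ci in range(len(marker_map.chromosomes)):
        sl = marker_map.chrom_slice(ci)
        sub = above[sl]
        if not sub.any():
            continue
        bounds = []
        run_start = None
        for i, val in enumerate(sub):
            if val and run_start is None:
                run_start = i
            elif not val and run_start is not None:
                bounds.append((run_start, i - 1))
                run_start = None
        if run_start is not None:
            bounds.append((run_start, len(sub) - 1))
        for a, b in bounds:
            seg = scan.lod[sl][a : b + 1]
            rows.append(
                {
                    "chrom": marker_map.chrom_name(ci),
                    "start_pos": int(marker_map.pos[sl.start + a]),
                    "end_pos": int(marker_map.pos[sl.start + b]),
                    "n_markers": b - a + 1,
                    "peak_lod": float(np.nanmax(seg)),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "n_markers", "peak_lod"]
    )
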