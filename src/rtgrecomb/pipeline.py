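"""End-to-end orchestration for one mother-daughter RTG pair.

Runs genotyping from allele-depth tables (or accepts pre-called genotype
matrices), short-run filtering, LOH tract assembly, recombination event
calling and count correction, and writes all tables plus a JSON summary and
a reproducibility log (package version, configuration hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import CorrectionParams, correct_counts
from .events import call_pair_events, events_to_frame, merge_events
from .genotypes import (
    GenotypingThresholds,
    call_genotypes,
    filter_short_runs_map,
    write_genotypes,
)
from .loh import summarize_loh, summarize_tracts, tracts_to_bed, tracts_to_frame
from .markers import MarkerMap

logger = logging.getLogger("rtgrecomb")


class PipelineError(RuntimeError):
    """Raised with the failing stage name when an input is unusable."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable run configuration; a run is reproducible from this + inputs."""

    marker_map: str
    chromosomes: str
    output_dir: str
    mother_depths: str | None = None
    daughter_depths: str | None = None
    genotype_matrix: str | None = None
    mother_name: str = "mother"
    daughter_name: str = "daughter"
    thresholds: GenotypingThresholds = field(default_factory=GenotypingThresholds)
    min_tract_markers: int = 3
    merge_max_gap: int = 5000
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["thresholds"] = dict(self.thresholds.__dict__)
        d["correction"] = dict(self.correction.__dict__)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "thresholds" in d:
            t = d["thresholds"]
            if "het_p1_range" in t:
                t["het_p1_range"] = tuple(t["het_p1_range"])
            if "het_p2_range" in t:
                t["het_p2_range"] = tuple(t["het_p2_range"])
            d["thresholds"] = GenotypingThresholds(**t)
        if "correction" in d:
            d["correction"] = CorrectionParams(**d["correction"])
        return cls(**d)


def _load_depths(path: str, marker_map: MarkerMap, stage: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, f"cannot read depth table {path}: {exc}") from exc
    required = {"chrom", "pos", "n_p1", "n_p2"}
    if not required <= set(df.columns):
        raise PipelineError(stage, f"depth table {path} lacks columns {required - set(df.columns)}")
    key = {(c, p): i for i, (c, p) in enumerate(
        zip((marker_map.chromosomes[ci].name for ci in marker_map.chrom_idx), marker_map.pos)
    )}
    n_p1 = np.zeros(marker_map.n_markers, dtype=np.int64)
    n_p2 = np.zeros(marker_map.n_markers, dtype=np.int64)
    for r in df.itertuples():
        i = key.get((r.chrom, r.pos))
        if i is not None:
            n_p1[i] = r.n_p1
            n_p2[i] = r.n_p2
    return n_p1, n_p2


def run_pipeline(config: RunConfig) -> dict:
    """Execute genotyping -> tracts -> events -> correction and write outputs.

    Returns the summary dict that is also written to ``summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        mmap = MarkerMap.read_tsv(config.marker_map, config.chromosomes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("marker_map", str(exc)) from exc

    if config.genotype_matrix:
        from .genotypes import read_genotypes

        try:
            calls = read_genotypes(config.genotype_matrix)
            mother = calls[config.mother_name]
            daughter = calls[config.daughter_name]
        except KeyError as exc:
            raise PipelineError("genotyping", f"strain missing from matrix: {exc}") from exc
    elif config.mother_depths and config.daughter_depths:
        m1, m2 = _load_depths(config.mother_depths, mmap, "genotyping")
        d1, d2 = _load_depths(config.daughter_depths, mmap, "genotyping")
        mother = call_genotypes(m1, m2, thresholds=config.thresholds)
        daughter = call_genotypes(d1, d2, thresholds=config.thresholds)
    else:
        raise PipelineError("genotyping", "need either depth tables or a genotype matrix")

    mother, log_m = filter_short_runs_map(mother, mmap, config.thresholds.min_adjacent_switch)
    daughter, log_d = filter_short_runs_map(daughter, mmap, config.thresholds.min_adjacent_switch)

    events, tracts, info = call_pair_events(
        mother, daughter, mmap, min_markers=config.min_tract_markers
    )
    merged, merge_log = merge_events(events, config.merge_max_gap)

    n_nrloh = sum(1 for t in tracts if t.reciprocity == "nrLOH")
    corrected = correct_counts(info["n_co"], n_nrloh, config.correction)

    write_genotypes(
        out / "genotypes.tsv",
        mmap,
        {config.mother_name: mother, config.daughter_name: daughter},
    )
    tracts_to_frame(tracts).to_csv(out / "tracts.tsv", sep="\t", index=False)
    tracts_to_bed(tracts).to_csv(out / "tracts.bed", sep="\t", index=False, header=False)
    events_to_frame(merged).to_csv(out / "events.tsv", sep="\t", index=False)
    (out / "correction.json").write_text(json.dumps(corrected.as_dict(), indent=1))

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_markers": mmap.n_markers,
        "n_four_zero_excluded": info["n_four_zero"],
        "n_no_call": info["n_na"],
        "n_short_runs_filtered": len(log_m) + len(log_d),
        "n_rloh": sum(1 for t in tracts if t.reciprocity == "rLOH"),
        "n_nrloh": n_nrloh,
        "observed_co": info["n_co"],
        "n_events": len(merged),
        "n_merges": len(merge_log),
        "event_kinds": events_to_frame(merged)["kind"].value_counts().to_dict(),
        "corrected": corrected.as_dict(),
        "loh_summary": summarize_loh(
            {config.mother_name: mother, config.daughter_name: daughter}
        ).to_dict(orient="records"),
        "tract_summary": summarize_tracts(tracts).to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    with open(out / "run.log", "w") as fh:
        fh.write(f"rtgrecomb {__version__}\nseed {config.seed}\n")
        fh.write(f"config_hash {summary['config_hash']}\n")
        for entry in merge_log:
            fh.write(f"merge {entry}\n")
        for entry in log_m + log_d:
            fh.write(f"short_run {entry}\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
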