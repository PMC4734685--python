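"""Marker-map generation, meiosis simulation, truth replay, reads, sporulation, pedigrees."""

from dataclasses import replace

import numpy as np
import pytest

from rtgrecomb.events import build_pseudotetrad, call_pair_events
from rtgrecomb.genotypes import HET, NO_CALL, call_genotypes
from rtgrecomb.loh import THREE_ONE, classify_segregation_vectors
from rtgrecomb.markers import Chromosome
from rtgrecomb.simulate import (
    SimConfig,
    SimTruth,
    expected_events,
    make_marker_map,
    match_expected_calls,
    replay_truth,
    sample_reads,
    simulate_pedigree,
    simulate_rtg_pair,
    sporulate,
)


class TestMarkerMap:
    def test_expected_marker_count(self):
        cfg = SimConfig(
            chromosomes=[Chromosome("c", 1_000_000, 500_000, 500_100)],
            marker_spacing=200.0,
        )
        mmap = make_marker_map(cfg, 0)
        assert mmap.n_markers == pytest.approx(5000, rel=0.05)

    def test_deterministic_per_seed(self, small_config):
        a = make_marker_map(small_config, 42)
        b = make_marker_map(small_config, 42)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.p1_allele, b.p1_allele)
        c = make_marker_map(small_config, 43)
        assert not np.array_equal(a.pos, c.pos)

    def test_no_markers_in_centromeres(self, small_map, small_config):
        for ci, chrom in enumerate(small_config.chromosomes):
            sl = small_map.chrom_slice(ci)
            pos = small_map.pos[sl]
            assert not np.any((pos >= chrom.cen_start) & (pos <= chrom.cen_end))

    def test_parental_alleles_differ(self, small_map):
        assert np.all(small_map.p1_allele != small_map.p2_allele)

    def test_spacing_longer_than_chromosome_rejected(self):
        cfg = SimConfig(
            chromosomes=[Chromosome("c", 1000, 400, 500)], marker_spacing=2000.0
        )
        with pytest.raises(ValueError):
            make_marker_map(cfg, 0)

    def test_tsv_round_trip(self, small_map, tmp_path):
        small_map.write_tsv(tmp_path / "m.tsv", tmp_path / "c.tsv")
        from rtgrecomb.markers import MarkerMap

        back = MarkerMap.read_tsv(tmp_path / "m.tsv", tmp_path / "c.tsv")
        assert np.array_equal(back.pos, small_map.pos)
        assert back.chromosomes == small_map.chromosomes


class TestRtgPair:
    def test_zero_events_gives_all_het(self, small_map, small_config):
        cfg = replace(
            small_config, co_per_arm_fixed=0, nco_per_arm_mean=0.0
        )
        pair = simulate_rtg_pair(small_map, cfg, 3)
        assert np.all(pair.mother == HET)
        assert np.all(pair.daughter == HET)

    def test_truth_replay_is_bit_identical(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 4)
        _, mother, daughter = replay_truth(pair.truth, small_map, small_config)
        assert np.array_equal(mother, pair.mother)
        assert np.array_equal(daughter, pair.daughter)

    def test_truth_json_round_trip(self, small_map, small_config, tmp_path):
        pair = simulate_rtg_pair(small_map, small_config, 5)
        pair.truth.to_json(tmp_path / "t.json")
        back = SimTruth.from_json(tmp_path / "t.json")
        _, mother, _ = replay_truth(back, small_map, small_config)
        assert np.array_equal(mother, pair.mother)

    def test_chromatid_conservation(self, small_map, small_config):
        """Mother and daughter jointly carry the four simulated chromatids."""
        pair = simulate_rtg_pair(small_map, small_config, 6)
        chromatids, _, _ = replay_truth(pair.truth, small_map, small_config)
        for ci, chrom in enumerate(small_config.chromosomes):
            sl = small_map.chrom_slice(ci)
            emitted = sorted(
                map(tuple, np.vstack([pair.mother_haplotypes[:, sl],
                                      pair.daughter_haplotypes[:, sl]]))
            )
            simulated = sorted(map(tuple, chromatids[:, sl]))
            assert emitted == simulated

    def test_pseudotetrad_recovers_chromatids_up_to_order(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 7)
        tet, kept = build_pseudotetrad(pair.mother, pair.daughter)
        assert kept.all()
        for strain_rows, haps in ((tet[:2], pair.mother_haplotypes),
                                  (tet[2:], pair.daughter_haplotypes)):
            # within each strain the pseudo-tetrad fixes P1 to the first
            # chromatid, so compare per-marker content multisets
            assert np.array_equal(
                np.sort(strain_rows, axis=0), np.sort(haps, axis=0)
            )

    def test_segregation_override(self, small_map, small_config):
        seg = {c.name: (0, 2) for c in small_config.chromosomes}
        pair = simulate_rtg_pair(small_map, small_config, 8, segregation=seg)
        assert pair.truth.segregation == seg

    def test_caller_matches_truth_projection(self, small_map, small_config):
        for seed in range(25):
            pair = simulate_rtg_pair(small_map, small_config, 600 + seed)
            exp, summ = expected_events(pair.truth, small_map, small_config)
            events, _, info = call_pair_events(
                pair.mother, pair.daughter, small_map, min_markers=1
            )
            m = match_expected_calls(events, exp)
            assert m["precision"] == 1.0 and m["recall"] == 1.0
            assert info["n_co"] == summ["n_manifest_co"]


class TestSampleReads:
    def test_pure_parental_reads_without_error(self, small_map, small_config):
        cfg = replace(small_config, error_rate=0.0, depth_mean=100.0)
        calls = np.zeros(small_map.n_markers, dtype=np.int8)  # all HOM_P1
        n_p1, n_p2 = sample_reads(calls, cfg, 1)
        assert np.all(n_p2 == 0)
        assert n_p1.mean() == pytest.approx(100, rel=0.05)

    def test_genotyper_recovers_truth(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 21)
        n_p1, n_p2 = sample_reads(pair.mother, small_config, 22)
        calls = call_genotypes(n_p1, n_p2)
        called = calls != NO_CALL
        assert called.mean() > 0.95
        assert (calls[called] == pair.mother[called]).mean() > 0.99

    def test_zero_depth_yields_no_call(self, small_map, small_config):
        cfg = replace(small_config, depth_mean=0.0)
        n_p1, n_p2 = sample_reads(
            np.full(small_map.n_markers, HET, dtype=np.int8), cfg, 2
        )
        calls = call_genotypes(n_p1, n_p2)
        assert np.all(calls == NO_CALL)


class TestSporulation:
    def test_parent_homozygosity_segregates_4_0(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 31)
        spores, _ = sporulate(pair.mother_haplotypes, small_map, small_config, 32)
        hom = pair.mother != HET
        assert np.all(spores[:, hom] == pair.mother[hom])

    def test_no_new_events_duplicates_parent_haplotypes(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 33)
        spores, _ = sporulate(
            pair.mother_haplotypes, small_map, small_config, 34, co_mean=0.0, nco_mean=0.0
        )
        spore_contents = sorted(map(tuple, (spores // 2)))
        parents = sorted(
            map(tuple, np.repeat(pair.mother_haplotypes, 2, axis=0))
        )
        assert spore_contents == parents

    def test_het_markers_segregate_2_2_outside_conversions(self, small_map, small_config):
        pair = simulate_rtg_pair(small_map, small_config, 35)
        spores, truth = sporulate(pair.mother_haplotypes, small_map, small_config, 36)
        het = pair.mother == HET
        n_p2 = (spores // 2).sum(axis=0)
        uneven = het & (n_p2 != 2)
        # every 3:1 marker lies inside a recorded sporulation conversion tract
        in_gc = np.zeros(small_map.n_markers, dtype=bool)
        for e in truth.events:
            if e.gc is not None:
                in_gc[e.gc[0] : e.gc[1] + 1] = True
        assert np.all(in_gc[uneven])

    def test_haploid_parent_rejected(self, small_map, small_config):
        with pytest.raises(ValueError):
            sporulate(np.zeros((1, small_map.n_markers), np.int8),
                      small_map, small_config, 0)


class TestPedigree:
    def test_homozygosity_monotone_along_lineage(self, small_map, small_config):
        records = simulate_pedigree(small_map, small_config, 4, 41)
        fractions = [r.hom_fraction for r in records]
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_fixed_loh_persists_with_parent_of_origin(self, small_map, small_config):
        records = simulate_pedigree(small_map, small_config, 3, 42)
        prev = None
        for r in records:
            calls = r.pair.mother if r.followed == "mother" else r.pair.daughter
            if prev is not None:
                hom_before = prev != HET
                assert np.array_equal(calls[hom_before], prev[hom_before])
            prev = calls

    def test_single_passage_matches_direct_simulation(self, small_map, small_config):
        records = simulate_pedigree(small_map, small_config, 1, 43)
        assert len(records) == 1
        assert records[0].pair.truth.events is not None

    def test_invalid_passages(self, small_map, small_config):
        with pytest.raises(ValueError):
            simulate_pedigree(small_map, small_config, 0, 1)


class TestGcTractLengths:
    def test_emitted_nrloh_lengths_match_configuration(self, small_map, small_config):
        """Mean visible conversion span recovers the configured mean within 10%."""
        cfg = replace(
            small_config, co_per_arm_fixed=0, nco_per_arm_mean=3.0
        )
        spans = []
        for seed in range(120):
            pair = simulate_rtg_pair(small_map, cfg, 700 + seed)
            pat = classify_segregation_vectors(pair.mother, pair.daughter)
            for e in pair.truth.events:
                if e.gc is None:
                    continue
                lo, hi = e.gc
                if np.any(pat[lo : hi + 1] == THREE_ONE):
                    spans.append(
                        int(small_map.pos[hi] - small_map.pos[lo]) + 1
                    )
        assert len(spans) > 800
        # the visible span is bounded by the outermost markers inside the
        # tract, which trims about one marker spacing from each end
        expected = small_config.gc_len_mean - 2 * small_config.marker_spacing
        assert np.mean(spans) == pytest.approx(expected, rel=0.1)


def test_detection_rate_matches_enumeration(small_map, small_config):
    """Empirical CO detection over many meioses matches the exact model."""
    from rtgrecomb.detection import detection_probability

    for k in (1, 2):
        cfg = replace(
            small_config, co_per_arm_fixed=k, nco_per_arm_mean=0.0, gc_with_co=0.0
        )
        detected = total = 0
        for seed in range(150):
            pair = simulate_rtg_pair(small_map, cfg, 3000 + 1000 * k + seed)
            _, summ = expected_events(pair.truth, small_map, cfg)
            detected += summ["n_manifest_co"]
            total += summ["n_true_co"]
        p = float(detection_probability(k))
        se = np.sqrt(p * (1 - p) / total)
        assert abs(detected / total - p) <= 3.5 * se
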