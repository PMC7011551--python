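import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from rohscan.roh_detection import ROHParams, ROHSegment, detect_roh
from rohscan.roh_islands import (
    adjacent_r2,
    annotate_island_ld,
    call_islands,
    overlap_with_scores,
    roh_frequency,
)
from rohscan.synthetic_data import IslandSpec, SimConfig, simulate_panel


def _markers(n, chrom="1", step=100_000):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chromosome": chrom,
            "position_bp": np.arange(1, n + 1) * step,
        }
    )


class TestFrequencyTrack:
    def test_no_segments_gives_zero_fractions(self):
        track = roh_frequency([], _markers(10), n_samples=5)
        assert (track["fraction"] == 0).all()

    def test_direct_count(self):
        markers = _markers(10)
        segs = [
            ROHSegment(f"x{i}", "1", 450_000, 650_000, 3, 0, 0) for i in range(3)
        ]
        track = roh_frequency(segs, markers, n_samples=10)
        covered = track[(track["position_bp"] >= 450_000) & (track["position_bp"] <= 650_000)]
        assert (covered["fraction"] == 0.3).all()
        assert (track.loc[~track.index.isin(covered.index), "fraction"] == 0).all()

    def test_same_sample_overlap_raises_not_double_counts(self):
        segs = [
            ROHSegment("x0", "1", 100_000, 400_000, 4, 0, 0),
            ROHSegment("x0", "1", 300_000, 600_000, 4, 0, 0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            roh_frequency(segs, _markers(10), n_samples=5)

    def test_unknown_chromosome_raises(self):
        segs = [ROHSegment("x0", "7", 1, 100_000, 2, 0, 0)]
        with pytest.raises(KeyError):
            roh_frequency(segs, _markers(5), n_samples=2)

    def test_coverage_conservation(self, sim_cohort):
        """Sum of per-SNP cover counts equals the sum over segments of the
        markers each segment contains."""
        panel, _, _ = sim_cohort
        segs = detect_roh(panel, ROHParams(min_snps=25))
        track = roh_frequency(segs, panel.markers, panel.n_samples)
        chroms = panel.markers["chromosome"].to_numpy()
        pos = panel.markers["position_bp"].to_numpy()
        per_seg = sum(
            int(((chroms == s.chromosome) & (pos >= s.start_bp) & (pos <= s.end_bp)).sum())
            for s in segs
        )
        assert track["n_covered"].sum() == per_seg


class TestCallIslands:
    @staticmethod
    def _track(fracs, chrom="1", step=100_000):
        t = _markers(len(fracs), chrom, step)
        t["fraction"] = fracs
        t["n_covered"] = 0
        return t

    def test_uniform_subthreshold_track_has_no_islands(self):
        assert call_islands(self._track([0.1] * 50)) == []

    def test_planted_run_becomes_one_island(self):
        fracs = [0.05] * 20 + [0.35] * 30 + [0.05] * 20
        islands = call_islands(self._track(fracs))
        assert len(islands) == 1
        (isl,) = islands
        assert isl.n_snps == 30
        assert isl.start_bp == 21 * 100_000
        assert isl.end_bp == 50 * 100_000
        assert isl.peak_fraction == pytest.approx(0.35)

    def test_threshold_is_strictly_greater_than(self):
        """A fraction exactly at the 20% threshold does not qualify."""
        fracs = [0.20] * 30
        assert call_islands(self._track(fracs), threshold=0.20) == []
        fracs = [0.2000001] * 30
        assert len(call_islands(self._track(fracs), threshold=0.20)) == 1

    def test_min_island_snps_drops_short_runs(self):
        fracs = [0.05] * 10 + [0.4] * 3 + [0.05] * 10
        assert call_islands(self._track(fracs), min_island_snps=5) == []

    def test_nearby_runs_joined_across_small_gaps(self):
        fracs = [0.4] * 6 + [0.1] * 2 + [0.4] * 6
        joined = call_islands(self._track(fracs), max_join_gap_bp=500_000)
        assert len(joined) == 1 and joined[0].n_snps == 12
        split = call_islands(self._track(fracs), max_join_gap_bp=100_000)
        assert len(split) == 2

    def test_chromosome_order_invariance_and_no_overlap(self):
        fracs = [0.3] * 8 + [0.05] * 10 + [0.3] * 8
        t1 = pd.concat(
            [self._track(fracs, "1"), self._track(fracs, "2")], ignore_index=True
        )
        t2 = pd.concat(
            [self._track(fracs, "2"), self._track(fracs, "1")], ignore_index=True
        )
        key = lambda i: (i.chromosome, i.start_bp, i.end_bp, i.n_snps)
        i1 = sorted(map(key, call_islands(t1)))
        i2 = sorted(map(key, call_islands(t2)))
        assert i1 == i2
        for chrom in ("1", "2"):
            spans = sorted(
                (i.start_bp, i.end_bp) for i in call_islands(t1) if i.chromosome == chrom
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 < b0


class TestAdjacentR2:
    def test_duplicated_columns_have_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        panel = make_panel(np.column_stack([col, col]))
        assert adjacent_r2(panel, np.array([0, 1])) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 1, 1, 1, 1, 2])
        panel = make_panel(np.column_stack([a, b]))
        # r = 2 / sqrt(4 * 2) -> r^2 = 0.5
        assert adjacent_r2(panel, np.array([0, 1])) == pytest.approx(0.5)

    def test_independent_snps_have_near_zero_r2(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.5, size=(10_000, 30)).astype(np.int8)
        assert adjacent_r2(make_panel(d), np.arange(30)) < 0.01

    def test_degenerate_pairs_flagged(self):
        d = np.zeros((6, 2), dtype=np.int8)  # no variance anywhere
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isnan(adjacent_r2(make_panel(d), np.array([0, 1])))


class TestScoreOverlap:
    def _island(self, chrom="1", start=100_000, end=1_000_000):
        from rohscan.roh_islands import ROHIsland

        return ROHIsland("P", chrom, start, end, 10, 0.4, 0.3)

    def test_empty_score_table_gives_empty_report(self):
        tab = pd.DataFrame(columns=["snp", "chromosome", "position", "score"])
        assert overlap_with_scores([self._island()], tab).empty

    def test_single_contained_snp_has_rank_one(self):
        tab = pd.DataFrame(
            {"snp": ["m1"], "chromosome": ["1"], "position": [900_000], "score": [2.5]}
        )
        rep = overlap_with_scores([self._island()], tab)
        assert len(rep) == 1
        assert rep["score_rank"].iloc[0] == 1

    def test_containment_count_matches_brute_force(self):
        rng = np.random.default_rng(12)
        pos = rng.integers(1, 10_000_000, size=100)
        tab = pd.DataFrame(
            {
                "snp": [f"m{i}" for i in range(100)],
                "chromosome": "1",
                "position": pos,
                "score": rng.normal(size=100),
            }
        )
        islands = [self._island("1", 1_000_000, 2_000_000), self._island("1", 5_000_000, 6_000_000)]
        rep = overlap_with_scores(islands, tab)
        brute = sum(
            int(a <= p <= b)
            for p in pos
            for a, b in [(1_000_000, 2_000_000), (5_000_000, 6_000_000)]
        )
        assert len(rep) == brute


class TestPlantedIslandRecovery:
    def test_island_called_with_high_span_coverage_and_ld_enrichment(self):
        """A shared homozygous haplotype carried by 35% of one population
        is recovered as a single island covering >= 90% of the planted
        region, with adjacent-SNP r-squared enriched over the chromosome."""
        spec = IslandSpec("P", "1", 8_000_000, 12_000_000, carrier_freq=0.35)
        cfg = SimConfig(
            seed=5,
            n_samples=(60,),
            population_labels=("P",),
            n_chromosomes=2,
            chromosome_length_bp=30_000_000,
            n_snps_per_chromosome=900,
            tracts_per_sample=(0.5,),
            islands=(spec,),
            genotyping_error_rate=0.001,
            missing_rate=0.002,
        )
        panel, truth = simulate_panel(cfg)
        segs = detect_roh(panel, ROHParams(min_snps=30))
        track = roh_frequency(segs, panel.markers, panel.n_samples)
        islands = call_islands(track, threshold=0.20, population="P")
        on_chrom = [i for i in islands if i.chromosome == "1"]
        assert len(on_chrom) == 1
        (isl,) = on_chrom
        overlap = min(isl.end_bp, spec.end_bp) - max(isl.start_bp, spec.start_bp) + 1
        assert overlap / (spec.end_bp - spec.start_bp + 1) >= 0.90
        annotate_island_ld([isl], panel)
        assert isl.r2_ratio > 1.0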