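"""Replication-timing quintiles and mutation-cluster detection."""

import numpy as np
import pytest
from scipy import stats

import apobecsig as a
from apobecsig.topography import (
    assign_timing_quintiles, cluster_class_counts, detect_clusters,
    mutations_per_quintile, tcw_to_t_fraction_per_quintile,
)
from apobecsig.variants import SomaticVariant


def _uniform_track(n_bins=100, width=1000, value=None):
    return [("chr1", i * width, (i + 1) * width,
             float(n_bins - i) if value is None else value)
            for i in range(n_bins)]


class TestAssignQuintiles:
    def test_rank_partition_of_graded_values(self):
        quintiles = assign_timing_quintiles(_uniform_track())
        # values decrease along the contig; early-is-high puts the first
        # 20 bins in Q1, the next 20 in Q2, ...
        for contig, start, end, value, q in quintiles.intervals:
            assert q == start // 20_000 + 1

    def test_tie_break_by_genomic_order(self):
        quintiles = assign_timing_quintiles(_uniform_track(value=7.0))
        per_q = {q: 0 for q in range(1, 6)}
        for *_, q in quintiles.intervals:
            per_q[q] += 1
        assert all(v == 20 for v in per_q.values())
        assert quintiles.quintile_of("chr1", 1) == 1
        assert quintiles.quintile_of("chr1", 99_999) == 5

    def test_early_is_low_dialect_flips(self):
        track = _uniform_track(n_bins=10)
        high = assign_timing_quintiles(track, early_is_high=True)
        low = assign_timing_quintiles(track, early_is_high=False)
        assert high.quintile_of("chr1", 1) == 1
        assert low.quintile_of("chr1", 1) == 5

    def test_generator_round_trip(self, big_genome):
        track = a.generate_timing_track(big_genome, 60, seed=31)
        quintiles = assign_timing_quintiles(
            [(c, s, e, v) for c, s, e, v in track.intervals])
        for (c, s, e, v), truth_q in zip(track.intervals, track.quintiles):
            assert quintiles.quintile_of(c, s + 1) == truth_q

    def test_balanced_assayed_length(self):
        quintiles = assign_timing_quintiles(_uniform_track())
        lengths = [quintiles.assayed_length(q) for q in range(1, 6)]
        assert max(lengths) - min(lengths) <= 1000  # one bin

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            assign_timing_quintiles([])


class TestMutationsPerQuintile:
    def _variants_at(self, positions):
        return [SomaticVariant("chr1", p, "C", "T") for p in positions]

    def test_uniform_planting_flat_normalized_vector(self):
        quintiles = assign_timing_quintiles(_uniform_track())
        rng = np.random.default_rng(1)
        variants = self._variants_at(rng.integers(1, 100_000, size=5000))
        counts = mutations_per_quintile(variants, quintiles)
        assert counts.normalized.max() == 1.0
        assert (counts.normalized > 0.85).all()

    def test_biased_q1_dominates(self):
        quintiles = assign_timing_quintiles(_uniform_track())
        rng = np.random.default_rng(2)
        q1 = rng.integers(1, 20_000, size=2000)        # Q1 bins
        rest = rng.integers(20_001, 100_000, size=4000)
        counts = mutations_per_quintile(self._variants_at(np.r_[q1, rest]), quintiles)
        assert counts.counts.argmax() == 0
        assert np.allclose(counts.normalized[1:], 0.5, atol=0.1)

    def test_off_track_dropped_and_counted(self):
        quintiles = assign_timing_quintiles(_uniform_track(n_bins=10))
        variants = self._variants_at([5, 500_000])
        counts = mutations_per_quintile(variants, quintiles)
        assert counts.counts.sum() == 1 and counts.n_unassigned == 1

    def test_chi_square_null_calibration(self):
        """Identical multinomial groups: p is approximately uniform, so
        rejections at 0.05 happen about 5% of the time."""
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.multinomial(400, [0.2] * 5)
            y = rng.multinomial(400, [0.2] * 5)
            _, p, _, _ = stats.chi2_contingency(np.vstack([x, y]))
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_group_comparison_attached(self):
        quintiles = assign_timing_quintiles(_uniform_track())
        rng = np.random.default_rng(4)
        g1 = mutations_per_quintile(
            self._variants_at(rng.integers(1, 100_000, size=3000)), quintiles)
        g2 = mutations_per_quintile(
            self._variants_at(rng.integers(1, 40_000, size=3000)), quintiles, g1)
        assert g2.chi2_p is not None and g2.chi2_p < 1e-6


class TestTcwToTFraction:
    def test_pure_sbs2_cohort_high_everywhere(self, big_genome, big_index, refs):
        track = a.generate_timing_track(big_genome, 50, seed=41)
        variants, _ = a.plant_sbs_from_signatures(
            big_genome, 3000, {"SBS2": 1.0}, refs, seed=42,
            site_index=big_index, mito_mutations=0)
        quintiles = assign_timing_quintiles(
            [(c, s, e, v) for c, s, e, v in track.intervals])
        fractions = tcw_to_t_fraction_per_quintile(variants, quintiles, big_genome)
        # expected share = SBS2 mass on T[C>T]N channels
        from apobecsig.spectrum import channel_index
        expected = 100 * sum(refs.column("SBS2")[channel_index("T", "C", "T", t)]
                             for t in "ACGT")
        assert np.nanmin(fractions) > expected - 10
        assert np.nanmax(fractions) < expected + 10

    def test_zero_tc_to_tt_everywhere(self, big_genome, big_index, refs):
        vec = np.zeros(96)
        vec[16:32] = 1 / 16  # all C>G channels, no C>T mass at all
        sbs13 = a.SignatureSet(["only_cg"], vec[:, None])
        track = a.generate_timing_track(big_genome, 50, seed=43)
        variants, _ = a.plant_sbs_from_signatures(
            big_genome, 500, {"only_cg": 1.0}, sbs13, seed=44,
            site_index=big_index, mito_mutations=0)
        quintiles = assign_timing_quintiles(
            [(c, s, e, v) for c, s, e, v in track.intervals])
        fractions = tcw_to_t_fraction_per_quintile(variants, quintiles, big_genome)
        assert np.nanmax(fractions) == 0.0

    def test_early_biased_apobec_fraction_decreases(self, big_genome, big_index, refs):
        """Early-replication-biased SBS2 over a uniform background: the
        TC>TT share falls from Q1 to Q5."""
        track = a.generate_timing_track(big_genome, 50, seed=45)
        apobec, _ = a.plant_sbs_from_signatures(
            big_genome, 4000, {"SBS2": 1.0}, refs, seed=46,
            timing_track=track, timing_bias={1: 4, 2: 2, 3: 1, 4: 0.5, 5: 0.25},
            site_index=big_index, mito_mutations=0)
        flat, _ = a.plant_sbs_from_signatures(
            big_genome, 4000, {"SBS5": 1.0}, refs, seed=47,
            timing_track=track, timing_bias={q: 1 for q in range(1, 6)},
            site_index=big_index, mito_mutations=0)
        quintiles = assign_timing_quintiles(
            [(c, s, e, v) for c, s, e, v in track.intervals])
        fractions = tcw_to_t_fraction_per_quintile(apobec + flat, quintiles,
                                                   big_genome)
        assert fractions[0] > fractions[2] > fractions[4]

    def test_empty_quintile_is_nan(self):
        quintiles = assign_timing_quintiles(_uniform_track(n_bins=10))
        variants = [SomaticVariant("chr1", 100, "C", "T")]
        fractions = tcw_to_t_fraction_per_quintile(
            variants, quintiles, a.InMemoryReference({"chr1": "A" * 200_000}))
        assert np.isnan(fractions[1:]).all()


class TestDetectClusters:
    def test_six_tight_mutations_are_kataegis(self):
        variants = [SomaticVariant("chr1", 1000 + 100 * i, "C", "T")
                    for i in range(6)]
        (call,) = detect_clusters(variants)
        assert call.cluster_class == "kataegis" and call.n_members == 6

    def test_isolated_pair_is_omikli(self):
        variants = [SomaticVariant("chr1", 10_000, "C", "T"),
                    SomaticVariant("chr1", 15_000, "C", "T")]
        (call,) = detect_clusters(variants)
        assert call.cluster_class == "omikli" and call.n_members == 2

    def test_wide_run_of_many_is_dispersed(self):
        # 7 mutations 5 kb apart: too loose for kataegis, too many for omikli
        variants = [SomaticVariant("chr1", 10_000 + 5_000 * i, "C", "T")
                    for i in range(7)]
        counts = cluster_class_counts(detect_clusters(variants))
        assert counts == {"dispersed": 7, "omikli": 0, "kataegis": 0}

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        variants = [SomaticVariant("chr1", int(p), "C", "T")
                    for p in np.sort(rng.integers(1, 10_000_000, size=2000))]
        calls = detect_clusters(variants)
        assert sum(c.n_members for c in calls) == len(variants)

    def test_sparse_poisson_mostly_dispersed(self):
        """Uniform mutations at 1/Mb: the Poisson expectation of clustered
        (mostly omikli-pair) variants is ~2*(1-exp(-2e-2)) ~ 2%, so the
        dispersed share sits near 98%."""
        rng = np.random.default_rng(6)
        length, n = 100_000_000, 100
        dispersed = total = 0
        for _ in range(30):
            positions = np.sort(rng.integers(1, length, size=n))
            variants = [SomaticVariant("chr1", int(p), "C", "T") for p in positions]
            counts = cluster_class_counts(detect_clusters(variants))
            dispersed += counts["dispersed"]
            total += n
        gap_rate = n / length
        p_clustered = 2 * (1 - np.exp(-10_000 * gap_rate))  # neighbor within IMD
        share = dispersed / total
        assert share == pytest.approx(1 - p_clustered, abs=0.015)
        assert share >= 0.97
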