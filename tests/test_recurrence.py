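"""Recurrence scoring: amplitude matrix projection, G-scores, permutation null
and q-values, peak calling, peel-off, focal/broad classification, and gene
alteration frequencies."""

import numpy as np
import pytest

from crossonc.genome import (
    GeneModel,
    GenomeModel,
    ProbeSet,
    Region,
    Segment,
    SegmentedProfile,
    StateThresholds,
)
from crossonc.recurrence import (
    AmplitudeMatrix,
    GScoreTrack,
    amplitude_matrix,
    call_peaks,
    classify_focal_broad,
    g_score,
    gene_alteration_frequency,
    gene_sample_states,
    peel_off,
    permutation_null_q,
    score_recurrent,
)


def grid_probes(n=100, spacing=1000, chrom="chr1"):
    genome = GenomeModel("g", [(chrom, n * spacing + spacing, max(1, n * spacing // 3))])
    return ProbeSet(
        genome,
        {chrom: np.arange(n) * spacing + spacing // 2},
        {chrom: [f"p{i}" for i in range(n)]},
    )


def seg_profile(probes, sample_id, pieces):
    """pieces: list of (first_probe, last_probe_inclusive, mean)."""
    th = StateThresholds()
    chrom = probes.chroms[0]
    pos = probes.positions[chrom]
    prof = SegmentedProfile(sample_id)
    prof.segments[chrom] = [
        Segment(
            Region(chrom, int(pos[a]), int(pos[b]) + 1), b - a + 1, m, th.state(m)
        )
        for a, b, m in pieces
    ]
    return prof


class TestAmplitudeMatrix:
    def test_single_segment_fills_all_markers(self):
        probes = grid_probes(20)
        prof = seg_profile(probes, "s1", [(0, 19, 0.5)])
        mat = amplitude_matrix([prof], probes)
        np.testing.assert_allclose(mat.values, 0.5)

    def test_hand_built_two_sample_case(self):
        probes = grid_probes(10)
        p1 = seg_profile(probes, "s1", [(0, 4, 0.3), (5, 9, -0.7)])
        p2 = seg_profile(probes, "s2", [(0, 9, 0.0)])
        mat = amplitude_matrix([p1, p2], probes)
        np.testing.assert_allclose(mat.values[:, 0], [0.3] * 5 + [-0.7] * 5)
        np.testing.assert_allclose(mat.values[:, 1], 0.0)

    def test_uncovered_marker_rejected(self):
        probes = grid_probes(10)
        prof = seg_profile(probes, "s1", [(0, 4, 0.3)])  # markers 5..9 uncovered
        with pytest.raises(ValueError, match="not covered"):
            amplitude_matrix([prof], probes)


class TestGScore:
    def test_all_zero_matrix_scores_zero(self):
        probes = grid_probes(10)
        mat = AmplitudeMatrix(np.zeros((10, 5)), probes, [f"s{i}" for i in range(5)])
        assert np.all(g_score(mat, direction="loss") == 0)
        assert np.all(g_score(mat, direction="gain") == 0)

    def test_hand_arithmetic_single_carrier(self):
        # one of 10 samples at -1.0 with theta_loss=0.1 -> G = (1.0-0.1)/10
        probes = grid_probes(3)
        vals = np.zeros((3, 10))
        vals[1, 0] = -1.0
        mat = AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(10)])
        g = g_score(mat, direction="loss")
        assert g[1] == pytest.approx(0.09)
        assert g[0] == g[2] == 0.0

    def test_subthreshold_amplitudes_score_zero(self):
        probes = grid_probes(5)
        rng = np.random.default_rng(0)
        vals = rng.uniform(-0.09, 0.09, (5, 8))
        mat = AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(8)])
        assert np.all(g_score(mat, direction="loss") == 0)

    def test_translation_monotone(self, rng):
        probes = grid_probes(8)
        vals = rng.normal(0, 0.3, (8, 6))
        mat = AmplitudeMatrix(vals.copy(), probes, [f"s{i}" for i in range(6)])
        g0 = g_score(mat, direction="loss")
        vals[3, 2] -= 1.0  # push one entry deeper
        mat2 = AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(6)])
        g1 = g_score(mat2, direction="loss")
        assert np.all(g1 >= g0)


class TestPermutationNull:
    def _cohort(self, seed=0, n_markers=60, n_samples=12, carrier_frac=0.0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 0.01, (n_markers, n_samples))
        carriers = rng.random(n_samples) < carrier_frac
        vals[20:30, carriers] = -1.0
        probes = grid_probes(n_markers)
        return AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(n_samples)])

    def test_equal_g_receives_equal_p(self):
        mat = self._cohort(carrier_frac=0.5)
        track = permutation_null_q(mat, "loss", 200, 0)
        g, p = track.g, track.p
        for val in np.unique(g):
            assert len(np.unique(p[g == val])) == 1

    def test_p_monotone_nonincreasing_in_g(self):
        mat = self._cohort(carrier_frac=0.4, seed=3)
        track = permutation_null_q(mat, "loss", 200, 0)
        order = np.argsort(track.g)
        assert np.all(np.diff(track.p[order]) <= 1e-15)

    def test_p_floor_respected(self):
        mat = self._cohort(carrier_frac=0.6, seed=1)
        n_perm = 200
        track = permutation_null_q(mat, "loss", n_perm, 0)
        floor = 1.0 / (1.0 + n_perm * mat.values.shape[0])
        assert np.all(track.p >= floor - 1e-15)
        assert np.all(track.q >= track.p - 1e-15)

    def test_planted_deletion_significant_across_locus(self):
        mat = self._cohort(carrier_frac=0.5, seed=7, n_samples=20)
        track = permutation_null_q(mat, "loss", 500, 0)
        assert np.all(track.q[20:30] < 0.1)
        assert np.all(track.q[:20] > 0.1)


class TestCallPeaks:
    def _track(self, q, g, probes):
        return GScoreTrack("loss", np.asarray(g, float), np.asarray(q, float),
                           np.asarray(q, float))

    def test_no_subthreshold_marker_yields_empty(self):
        probes = grid_probes(10)
        track = self._track(np.ones(10), np.zeros(10), probes)
        assert call_peaks(track, probes) == []

    def test_contiguous_run_becomes_single_peak(self):
        probes = grid_probes(100)
        q = np.ones(100)
        q[40:61] = 0.01
        g = np.zeros(100)
        g[50] = 0.5
        peaks = call_peaks(self._track(q, g, probes), probes)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.marker_span == (40, 61)
        assert pk.q_min_pos == int(probes.positions["chr1"][50]) or pk.q_min == 0.01

    def test_default_threshold_is_0_1(self):
        probes = grid_probes(10)
        q = np.full(10, 0.09)
        peaks = call_peaks(self._track(q, np.ones(10), probes), probes)
        assert len(peaks) == 1  # q=0.09 < default 0.1


class TestPeelOff:
    def test_neutral_sample_column_unchanged(self):
        probes = grid_probes(30)
        vals = np.zeros((30, 3))
        vals[10:20, 0] = -1.0
        mat = AmplitudeMatrix(vals.copy(), probes, ["c", "n1", "n2"])
        from crossonc.recurrence import Peak

        pos = probes.positions["chr1"]
        peak = Peak("loss", Region("chr1", int(pos[10]), int(pos[19]) + 1),
                    (10, 20), 0.01, int(pos[12]), 0.3)
        out = peel_off(mat, peak)
        np.testing.assert_array_equal(out.values[:, 1], vals[:, 1])
        np.testing.assert_array_equal(out.values[:, 2], vals[:, 2])

    def test_g_zero_after_all_carriers_peeled(self):
        probes = grid_probes(40)
        vals = np.zeros((40, 6))
        vals[15:25, :3] = -1.0
        mat = AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(6)])
        track = permutation_null_q(mat, "loss", 200, 0)
        peaks = call_peaks(track, probes)
        out = peel_off(mat, peaks[0])
        g_after = g_score(out, direction="loss")
        assert np.all(g_after[15:25] == 0)

    def test_two_disjoint_drivers_recovered_across_iterations(self):
        rng = np.random.default_rng(2)
        probes = grid_probes(100)
        vals = rng.normal(0, 0.01, (100, 20))
        vals[10:18, rng.random(20) < 0.6] += -1.0
        vals[60:70, rng.random(20) < 0.5] += -0.8
        mat = AmplitudeMatrix(vals, probes, [f"s{i}" for i in range(20)])
        _, peaks = score_recurrent(mat, directions=("loss",), n_perm=300, seed=0)
        spans = sorted(p.marker_span for p in peaks)
        assert any(a <= 14 <= b for a, b in spans)
        assert any(a <= 64 <= b for a, b in spans)
        assert len(peaks) >= 2


class TestFocalBroad:
    def test_full_arm_is_broad(self, toy_genome):
        p_arm, q_arm = toy_genome.arms("chr1")
        assert classify_focal_broad(q_arm, toy_genome) is True

    def test_small_region_is_focal(self, toy_genome):
        # 0.4 Mb on the 6-Mb q arm
        assert classify_focal_broad(Region("chr1", 5_000_000, 5_400_000), toy_genome) is False

    def test_boundary_fraction_counts_as_broad(self, toy_genome):
        # exactly half the 6-Mb q arm
        r = Region("chr1", 4_000_000, 7_000_000)
        assert classify_focal_broad(r, toy_genome) is True


class TestGeneFrequency:
    def test_no_alterations_zero_everywhere(self):
        probes = grid_probes(20)
        profs = [seg_profile(probes, f"s{i}", [(0, 19, 0.0)]) for i in range(4)]
        genes = [GeneModel("G1", Region("chr1", 5_000, 8_000))]
        freq = gene_alteration_frequency(profs, genes, direction="loss")
        assert freq["G1"] == (0, 4, 0.0)

    def test_hand_fixture_two_of_three_carriers(self):
        probes = grid_probes(20)
        profs = [
            seg_profile(probes, "s1", [(0, 9, -0.8), (10, 19, 0.0)]),
            seg_profile(probes, "s2", [(0, 9, -0.9), (10, 19, 0.0)]),
            seg_profile(probes, "s3", [(0, 19, 0.0)]),
        ]
        genes = [GeneModel("G1", Region("chr1", 2_000, 6_000))]
        freq = gene_alteration_frequency(profs, genes, direction="loss")
        count, n, frac = freq["G1"]
        assert (count, n) == (2, 3)
        assert frac == pytest.approx(2 / 3)

    def test_unknown_chromosome_rejected(self, toy_genome):
        probes = grid_probes(10)
        profs = [seg_profile(probes, "s1", [(0, 9, 0.0)])]
        genes = [GeneModel("G1", Region("chrX", 0, 100))]
        with pytest.raises(ValueError, match="chrX"):
            gene_alteration_frequency(profs, genes, genome=toy_genome)


class TestGeneSampleStates:
    def test_most_extreme_overlapping_state_wins(self):
        probes = grid_probes(20)
        prof = seg_profile(probes, "s1", [(0, 9, -1.2), (10, 19, 0.2)])
        genes = [
            GeneModel("DEEP", Region("chr1", 2_000, 4_000)),
            GeneModel("GAINED", Region("chr1", 12_000, 14_000)),
            GeneModel("SPAN", Region("chr1", 8_000, 12_000)),
        ]
        states = gene_sample_states([prof], genes)
        assert states.loc["s1", "DEEP"] == -2
        assert states.loc["s1", "GAINED"] == 1
        assert states.loc["s1", "SPAN"] == -2  # deepest overlapping segment wins
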