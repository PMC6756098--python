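"""Segmentation: circular max-t statistic, permutation significance, CBS
recursion, the penalized DP segmenter, level merging, and two-segmenter
concordance/consensus."""

import itertools

import numpy as np
import pytest

from crossonc.genome import GenomeModel, ProbeSet, Region, Segment, StateThresholds
from crossonc.segmentation import (
    CbsParams,
    _dp_intervals,
    cbs_segment,
    consensus_states,
    max_t_split,
    merge_levels,
    penalized_objective,
    penalized_segment,
    probe_state_concordance,
    probe_states,
    split_pvalue,
)

from conftest import make_profile


# ---------------------------------------------------------------------------
# independent oracles


def max_t_oracle(x: np.ndarray, min_width: int = 2):
    """Exhaustive O(n^2) scan over all circular splits, direct slice arithmetic."""
    n = len(x)
    best = (-1.0, (0, 0))
    for i in range(n):
        for j in range(i + 1, n + 1):
            L = j - i
            if L < min_width or n - L < min_width:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            ss = ((arc - arc.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum()
            sp2 = max(ss, 0.0) / (n - 2)
            denom = np.sqrt(sp2 * (1 / L + 1 / (n - L)))
            diff = abs(arc.mean() - rest.mean())
            t = (np.inf if diff > 0 else 0.0) if denom == 0 else diff / denom
            if t > best[0] or (t == best[0] and (i, j) < best[1]):
                best = (t, (i, j))
    return best[1][0], best[1][1], best[0]


def best_bounded_enumeration(x: np.ndarray, lam: float, max_breakpoints: int = 3):
    """Least-squares objective over ALL segmentations with <= max_breakpoints,
    by explicit enumeration of breakpoint combinations."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i, j):
        return (Q[j] - Q[i]) - (S[j] - S[i]) ** 2 / (j - i)

    best = cost(0, n) + lam
    for k in range(1, max_breakpoints + 1):
        for bps in itertools.combinations(range(1, n), k):
            bounds = (0,) + bps + (n,)
            obj = sum(cost(a, b) for a, b in zip(bounds, bounds[1:])) + lam * (k + 1)
            if obj < best:
                best = obj
    return best


def chrom_profile(values, spacing: int = 1000):
    """A single-chromosome profile over an evenly spaced grid."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    genome = GenomeModel("g", [("chr1", (n + 1) * spacing, max(1, n * spacing // 3))])
    probes = ProbeSet(
        genome,
        {"chr1": np.arange(n) * spacing + spacing // 2},
        {"chr1": [f"p{i}" for i in range(n)]},
    )
    return make_profile(probes, values)


# ---------------------------------------------------------------------------
# max_t_split


class TestMaxTSplit:
    def test_constant_vector_has_zero_t(self):
        res = max_t_split(np.zeros(20))
        assert res.t == 0.0

    def test_clean_step_splits_exactly_at_boundary(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        res = max_t_split(x)
        # the arc (0, 20] and its complement (20, 40] define the same partition
        # (internal boundary exactly at the step); the lexicographic tie-break
        # reports the smaller (i, j)
        assert {res.i, res.j} - {0, 40} == {20}
        assert res.t == np.inf

    def test_matches_exhaustive_oracle_on_random_vectors(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 61))
            x = rng.normal(0, 1, n)
            i, j, t = max_t_oracle(x)
            res = max_t_split(x)
            assert (res.i, res.j) == (i, j)
            assert res.t == pytest.approx(t, rel=1e-9)

    def test_too_short_returns_none(self):
        assert max_t_split(np.array([1.0, 2.0, 3.0])) is None


class TestSplitPvalue:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 50)
        res = max_t_split(x)
        p1 = split_pvalue(x, res.t, 100, np.random.default_rng(7))
        p2 = split_pvalue(x, res.t, 100, np.random.default_rng(7))
        assert p1 == p2

    def test_clean_step_reaches_permutation_floor(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.1, 100)
        res = max_t_split(x)
        p = split_pvalue(x, res.t, 200, np.random.default_rng(1))
        assert p == pytest.approx(1 / 201)

    def test_type_i_error_controlled_on_pure_noise(self):
        # at alpha=0.01 the rejection rate over noise replicates stays small
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            x = rng.normal(0, 1, 40)
            res = max_t_split(x)
            p = split_pvalue(x, res.t, 100, np.random.default_rng(1000 + k))
            rejections += p < 0.01
        assert rejections / n_rep <= 0.03


# ---------------------------------------------------------------------------
# cbs_segment


class TestCbsSegment:
    def test_constant_chromosome_single_segment(self):
        prof = chrom_profile(np.zeros(100))
        seg = cbs_segment(prof, CbsParams(n_perm=100), seed=0)
        assert len(seg.segments["chr1"]) == 1
        assert seg.segments["chr1"][0].n_probes == 100

    def test_two_level_signal_recovers_breakpoint(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(0, 0.1, 200)
        prof = chrom_profile(x)
        seg = cbs_segment(prof, CbsParams(n_perm=200), seed=0)
        segs = seg.segments["chr1"]
        assert len(segs) == 2
        assert abs(segs[0].n_probes - 100) <= 2
        # agrees with the exact least-squares DP on the same signal
        dp = penalized_segment(prof)
        assert abs(dp.segments["chr1"][0].n_probes - 100) <= 2

    def test_pure_noise_rarely_splits(self):
        rng = np.random.default_rng(11)
        singles = 0
        n_rep = 50
        for k in range(n_rep):
            prof = chrom_profile(rng.normal(0, 0.2, 150), spacing=1000)
            seg = cbs_segment(prof, CbsParams(alpha=0.01, n_perm=200), seed=k)
            singles += len(seg.segments["chr1"]) == 1
        assert singles / n_rep >= 0.95

    def test_tiling_invariant_with_missing_values(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.1, 120)
        x[[5, 50, 51, 110]] = np.nan
        prof = chrom_profile(x)
        seg = cbs_segment(prof, CbsParams(n_perm=100), seed=0)
        seg.validate_tiling(prof.probes)
        assert sum(s.n_probes for s in seg.segments["chr1"]) == 120

    def test_few_usable_probes_skips_chromosome(self):
        x = np.full(30, np.nan)
        x[:5] = 0.0
        prof = chrom_profile(x)
        seg = cbs_segment(prof, CbsParams(n_perm=100), seed=0)
        assert "chr1" not in seg.segments


# ---------------------------------------------------------------------------
# penalized_segment


class TestPenalizedSegment:
    def test_constant_signal_one_segment_any_penalty(self):
        for lam in (0.01, 0.5, 10.0):
            prof = chrom_profile(np.ones(50) * 0.3)
            seg = penalized_segment(prof, lam=lam)
            assert len(seg.segments["chr1"]) == 1

    def test_objective_matches_bounded_enumeration_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(10, 41))
            n_bp = int(rng.integers(0, 4))
            bps = np.sort(rng.choice(np.arange(1, n), size=n_bp, replace=False))
            levels = rng.normal(0, 1.5, n_bp + 1)
            x = np.empty(n)
            bounds = np.concatenate([[0], bps, [n]])
            for lev, (a, b) in zip(levels, zip(bounds, bounds[1:])):
                x[a:b] = lev
            x += rng.normal(0, 0.2, n)
            lam = 0.5
            intervals = _dp_intervals(x, lam)
            if len(intervals) <= 4:
                obj = penalized_objective(x, intervals, lam)
                oracle = best_bounded_enumeration(x, lam, 3)
                assert obj == pytest.approx(oracle, rel=1e-9)

    def test_clean_step_matches_cbs_breakpoint(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        prof = chrom_profile(x)
        dp = penalized_segment(prof, lam=0.5)
        cbs = cbs_segment(prof, CbsParams(n_perm=100), seed=0)
        assert [s.n_probes for s in dp.segments["chr1"]] == [30, 30]
        assert [s.n_probes for s in cbs.segments["chr1"]] == [30, 30]


# ---------------------------------------------------------------------------
# merge_levels


class TestMergeLevels:
    def _segs(self, means, n_probes):
        out, start = [], 0
        for m, n in zip(means, n_probes):
            out.append(Segment(Region("chr1", start, start + n * 10), n, m, 0))
            start += n * 10
        return out

    def test_single_segment_unchanged(self):
        segs = self._segs([0.5], [10])
        assert merge_levels(segs, 0.1) == segs

    def test_close_means_merge_with_weighted_mean(self):
        segs = self._segs([0.00, 0.05], [10, 30])
        merged = merge_levels(segs, 0.1)
        assert len(merged) == 1
        assert merged[0].mean == pytest.approx((0.00 * 10 + 0.05 * 30) / 40)
        assert merged[0].n_probes == 40

    def test_idempotent(self, rng):
        segs = self._segs(rng.normal(0, 0.3, 8), [5] * 8)
        once = merge_levels(segs, 0.15)
        twice = merge_levels(once, 0.15)
        assert [(s.mean, s.n_probes) for s in twice] == [
            (s.mean, s.n_probes) for s in once
        ]


# ---------------------------------------------------------------------------
# concordance / consensus


def two_segmentations(probes, means_a, means_b, split=50):
    """Two single-chromosome segmentations with one boundary at `split` probes."""
    from crossonc.genome import SegmentedProfile

    pos = probes.positions["chr1"]
    n = len(pos)

    def build(name, means, cut):
        p = SegmentedProfile(name)
        th = StateThresholds()
        p.segments["chr1"] = [
            Segment(Region("chr1", int(pos[0]), int(pos[cut - 1]) + 1), cut, means[0],
                    th.state(means[0])),
            Segment(Region("chr1", int(pos[cut]), int(pos[-1]) + 1), n - cut, means[1],
                    th.state(means[1])),
        ]
        return p

    return build("a", means_a, split), build("b", means_b, split)


class TestConcordance:
    def test_identical_segmentations_agree_fully(self, toy_probes):
        a, b = two_segmentations(toy_probes, (0.5, -0.5), (0.5, -0.5))
        rep = probe_state_concordance(a, b, toy_probes)
        assert rep.agreement == pytest.approx(1.0)
        assert rep.breakpoint_jaccard == 1.0

    def test_opposite_states_agree_nowhere(self, toy_probes):
        # chr2 has no segments in either profile; compare only chr1 probes
        a, b = two_segmentations(toy_probes, (0.5, 0.5), (0.0, 0.0))
        rep = probe_state_concordance(a, b, toy_probes)
        n1 = toy_probes.n_probes_chrom("chr1")
        n2 = toy_probes.n_probes_chrom("chr2")
        # chr1 disagrees everywhere; uncovered chr2 probes default neutral/neutral
        assert rep.confusion[2, 1] == n1  # gain called by a, neutral by b
        assert rep.agreement == pytest.approx(n2 / (n1 + n2))

    def test_hand_counted_agreement(self):
        genome = GenomeModel("g", [("chr1", 1000, 400)])
        probes = ProbeSet(
            genome, {"chr1": np.arange(10) * 100 + 50}, {"chr1": [f"p{i}" for i in range(10)]}
        )
        a, b = two_segmentations(probes, (0.5, 0.0), (0.5, 0.0), split=5)
        # shift b's boundary by one probe -> exactly one discordant probe
        b.segments["chr1"][0] = Segment(Region("chr1", 50, 551), 6, 0.5, 1)
        b.segments["chr1"][1] = Segment(Region("chr1", 551, 951), 4, 0.0, 0)
        rep = probe_state_concordance(a, b, probes)
        assert rep.agreement == pytest.approx(0.9)


class TestConsensus:
    def test_identical_inputs_identical_output_both_policies(self, toy_probes):
        a, b = two_segmentations(toy_probes, (0.5, -0.5), (0.5, -0.5))
        for policy in ("agree", "primary"):
            out = consensus_states(a, b, toy_probes, policy=policy)
            np.testing.assert_array_equal(out, probe_states(a, toy_probes, StateThresholds()))

    def test_all_neutral_second_segmenter_silences_agree_policy(self, toy_probes):
        a, b = two_segmentations(toy_probes, (0.5, -0.5), (0.0, 0.0))
        out = consensus_states(a, b, toy_probes, policy="agree")
        assert not np.any(out != 0)

    def test_partial_overlap_keeps_intersection_only(self, toy_probes):
        a, b = two_segmentations(toy_probes, (0.5, 0.0), (0.5, 0.0), split=50)
        pos = toy_probes.positions["chr1"]
        b.segments["chr1"][0] = Segment(Region("chr1", int(pos[0]), int(pos[29]) + 1), 30, 0.5, 1)
        b.segments["chr1"][1] = Segment(
            Region("chr1", int(pos[29]) + 1, int(pos[-1]) + 1), 70, 0.0, 0
        )
        out = consensus_states(a, b, toy_probes, policy="agree")
        sl = toy_probes.chrom_slice("chr1")
        assert np.sum(out[sl] == 1) == 30  # intersection of the two gain calls

    def test_unknown_policy_rejected(self, toy_probes):
        a, b = two_segmentations(toy_probes, (0.5, 0.0), (0.5, 0.0))
        with pytest.raises(ValueError, match="policy"):
            consensus_states(a, b, toy_probes, policy="vote")
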