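"""Copy-number segmentation.

Two segmenters define the copy-number profile:

* :func:`cbs_segment` — circular binary segmentation: recursively split each
  chromosome at the circular arc pair maximising the two-sample t statistic,
  accepting a split when a within-chromosome permutation p-value falls below
  alpha, then merge near-equal levels.
* :func:`penalized_segment` — an exact penalized least-squares segmenter
  (dynamic programming over SSE + lambda * #segments), the deterministic
  independent second method used for the concordance/consensus step.

Both operate per chromosome on the non-missing probes; missing probes are
absorbed into the covering segment so probe counts are conserved.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .genome import (
    GAIN,
    LOSS,
    NEUTRAL,
    ProbeSet,
    Region,
    SampleProfile,
    Segment,
    SegmentedProfile,
    StateThresholds,
)

logger = logging.getLogger("crossonc")

_STATES = (LOSS, NEUTRAL, GAIN)
MIN_USABLE_PROBES = 10  # chromosomes with fewer finite probes are skipped


@dataclass(frozen=True)
class CbsParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    merge_tol: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


class SplitResult(NamedTuple):
    i: int
    j: int
    t: float


def _chrom_rng(seed: int, sample_id: str, chrom: str) -> np.random.Generator:
    """Per-(sample, chromosome) RNG substream so results are order-independent."""
    sid = zlib.crc32(sample_id.encode()) & 0x7FFFFFFF
    cid = zlib.crc32(chrom.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), sid, cid]))


# ---------------------------------------------------------------------------
# circular max-t statistic


def max_t_split(values: Sequence[float], min_width: int = 2) -> SplitResult | None:
    """Best circular split of a value sequence.

    Over all boundary pairs ``0 <= i < j <= n`` with both the arc ``(i, j]``
    (``values[i:j]``) and its complement at least ``min_width`` long, return
    the pair maximising the absolute pooled two-sample t statistic between arc
    means.  Ties break to the smallest ``i`` then smallest ``j``.  Returns
    ``None`` when fewer than ``2 * min_width`` (or 4) usable values exist.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < max(4, 2 * min_width):
        return None
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    total, qtotal = S[-1], Q[-1]

    best_t, best_ij = -1.0, (0, 0)
    for L in range(min_width, n - min_width + 1):
        sum1 = S[L:] - S[:-L]          # arc sums for i = 0 .. n-L
        q1 = Q[L:] - Q[:-L]
        m1 = sum1 / L
        m2 = (total - sum1) / (n - L)
        ss = (q1 - sum1 * sum1 / L) + (qtotal - q1 - (total - sum1) ** 2 / (n - L))
        sp2 = np.maximum(ss, 0.0) / (n - 2)
        denom = np.sqrt(sp2 * (1.0 / L + 1.0 / (n - L)))
        diff = np.abs(m1 - m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, diff / denom, np.where(diff > 0, np.inf, 0.0))
        k = int(np.argmax(t))          # first max -> smallest i for this L
        tk = float(t[k])
        # a suffix arc (i, n] and the prefix arc (0, i] describe the same
        # partition; canonicalise to the lexicographically smaller pair so
        # float noise between the two equivalent scans cannot flip the result
        ij = (0, k) if k + L == n else (k, k + L)
        if tk > best_t or (tk == best_t and ij < best_ij):
            best_t, best_ij = tk, ij
    return SplitResult(best_ij[0], best_ij[1], best_t)


def _max_t_batch(V: np.ndarray, min_width: int = 2) -> np.ndarray:
    """Row-wise max circular-split |t| for a (B, n) batch (statistic only)."""
    B, n = V.shape
    P = np.concatenate([np.zeros((B, 1)), np.cumsum(V, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((B, 1)), np.cumsum(V * V, axis=1)], axis=1)
    total = P[:, -1:]
    qtotal = Q[:, -1:]
    out = np.zeros(B)
    for L in range(min_width, n - min_width + 1):
        sum1 = P[:, L:] - P[:, :-L]
        q1 = Q[:, L:] - Q[:, :-L]
        m1 = sum1 / L
        m2 = (total - sum1) / (n - L)
        ss = (q1 - sum1 * sum1 / L) + (qtotal - q1 - (total - sum1) ** 2 / (n - L))
        sp2 = np.maximum(ss, 0.0) / (n - 2)
        denom = np.sqrt(sp2 * (1.0 / L + 1.0 / (n - L)))
        diff = np.abs(m1 - m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, diff / denom, np.where(diff > 0, np.inf, 0.0))
        np.maximum(out, t.max(axis=1), out=out)
    return out


def split_pvalue(
    values: Sequence[float],
    t_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int = 2,
) -> float:
    """Permutation p-value for an observed max-t: shuffle the value order
    ``n_perm`` times and count permutations whose own max-t reaches ``t_obs``.

    ``p = (1 + #{t_perm >= t_obs}) / (1 + n_perm)``, so the floor is
    ``1 / (1 + n_perm)``.
    """
    x = np.asarray(values, dtype=float)
    V = rng.permuted(np.broadcast_to(x, (n_perm, x.size)), axis=1)
    t_perm = _max_t_batch(V, min_width)
    return (1.0 + int(np.sum(t_perm >= t_obs))) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# CBS recursion


def _cbs_intervals(
    x: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on a dense value vector; returns half-open index intervals."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        res = max_t_split(seg, params.min_width)
        if res is None or res.t <= 0:
            out.append((lo, hi))
            return
        p = split_pvalue(seg, res.t, params.n_perm, rng, params.min_width)
        if p >= params.alpha:
            out.append((lo, hi))
            return
        bounds = sorted({lo, lo + res.i, lo + res.j, hi})
        for a, b in zip(bounds, bounds[1:]):
            recurse(a, b)

    recurse(0, x.size)
    out.sort()
    return out


def _merge_interval_levels(
    x: np.ndarray, intervals: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    """Merge adjacent index intervals whose means differ by < tol (closest first)."""
    segs = [[a, b, float(x[a:b].mean())] for a, b in intervals]
    while len(segs) > 1:
        diffs = [abs(segs[k + 1][2] - segs[k][2]) for k in range(len(segs) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= tol:
            break
        a, b = segs[k], segs[k + 1]
        na, nb = a[1] - a[0], b[1] - b[0]
        merged = [a[0], b[1], (a[2] * na + b[2] * nb) / (na + nb)]
        segs[k : k + 2] = [merged]
    return [(a, b) for a, b, _ in segs]


def _intervals_to_segments(
    intervals: list[tuple[int, int]],
    used: np.ndarray,
    values: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    thresholds: StateThresholds,
) -> list[Segment]:
    """Convert used-index intervals into Segments tiling the full probe range.

    Segment boundaries fall at the full-grid index of each interval's first
    used probe, so missing probes are absorbed and counts are conserved.
    """
    n_full = positions.size
    starts_full = [0] + [int(used[a]) for a, _ in intervals[1:]]
    ends_full = starts_full[1:] + [n_full]
    segs = []
    for (a, b), fs, fe in zip(intervals, starts_full, ends_full):
        mean = float(values[used[a:b]].mean())
        segs.append(
            Segment(
                Region(chrom, int(positions[fs]), int(positions[fe - 1]) + 1),
                fe - fs,
                mean,
                thresholds.state(mean),
            )
        )
    return segs


def _segment_profile(
    profile: SampleProfile,
    thresholds: StateThresholds,
    interval_fn,
) -> SegmentedProfile:
    probes = profile.probes
    result = SegmentedProfile(profile.sample_id)
    for chrom in probes.chroms:
        vals = profile.chrom_values(chrom)
        used = np.flatnonzero(np.isfinite(vals))
        if used.size < MIN_USABLE_PROBES:
            logger.warning(
                "sample %s chromosome %s: only %d usable probes, skipping",
                profile.sample_id, chrom, used.size,
            )
            continue
        intervals = interval_fn(chrom, vals[used])
        result.segments[chrom] = _intervals_to_segments(
            intervals, used, vals, probes.positions[chrom], chrom, thresholds
        )
    return result


def cbs_segment(
    profile: SampleProfile,
    params: CbsParams = CbsParams(),
    thresholds: StateThresholds = StateThresholds(),
    seed: int = 0,
) -> SegmentedProfile:
    """Circular binary segmentation of one sample (all chromosomes)."""

    def fn(chrom: str, x: np.ndarray) -> list[tuple[int, int]]:
        rng = _chrom_rng(seed, profile.sample_id, chrom)
        intervals = _cbs_intervals(x, params, rng)
        return _merge_interval_levels(x, intervals, params.merge_tol)

    return _segment_profile(profile, thresholds, fn)


# ---------------------------------------------------------------------------
# penalized least-squares segmenter (the deterministic second method)


def _dp_intervals(x: np.ndarray, lam: float) -> list[tuple[int, int]]:
    """Exact minimiser of sum of segment SSE + lam * (#segments), O(n^2) DP."""
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    D = np.full(n + 1, np.inf)
    D[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(j)
        cost = (Q[j] - Q[i]) - (S[j] - S[i]) ** 2 / (j - i)
        cand = D[:j] + cost + lam
        k = int(np.argmin(cand))
        D[j] = cand[k]
        back[j] = k
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(back[bounds[-1]]))
    bounds.reverse()
    return list(zip(bounds, bounds[1:]))


def auto_penalty(x: np.ndarray) -> float:
    """BIC-style penalty ``4 * sigma^2 * log n`` with a robust first-difference
    MAD estimate of the probe noise.

    Each additional segment introduces two free parameters (its level and its
    boundary), each costing ``sigma^2 log n`` in SSE units; charging only one
    lets short spurious segments through at chromosome ends, where a split
    needs just one boundary.
    """
    n = x.size
    if n < 3:
        return 1.0
    d = np.diff(x)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0)
    sigma = max(float(sigma), 1e-8)
    return 4.0 * sigma * sigma * np.log(n)


def penalized_segment(
    profile: SampleProfile,
    lam: float | None = None,
    thresholds: StateThresholds = StateThresholds(),
) -> SegmentedProfile:
    """Exact penalized least-squares segmentation (deterministic)."""

    def fn(chrom: str, x: np.ndarray) -> list[tuple[int, int]]:
        penalty = auto_penalty(x) if lam is None else lam
        return _dp_intervals(x, penalty)

    return _segment_profile(profile, thresholds, fn)


def penalized_objective(x: np.ndarray, intervals: list[tuple[int, int]], lam: float) -> float:
    """SSE + lam * #segments of a given index segmentation (for cross-checks)."""
    sse = sum(float(((x[a:b] - x[a:b].mean()) ** 2).sum()) for a, b in intervals)
    return sse + lam * len(intervals)


# ---------------------------------------------------------------------------
# level merging on Segment lists


def merge_levels(segments: list[Segment], tol: float, thresholds: StateThresholds = StateThresholds()) -> list[Segment]:
    """Merge adjacent segments whose means differ by < tol (probe-weighted means).

    The closest pair merges first; the procedure is idempotent (afterwards all
    adjacent mean gaps are >= tol).
    """
    segs = [Segment(s.region, s.n_probes, s.mean, s.state) for s in segments]
    while len(segs) > 1:
        diffs = [abs(segs[k + 1].mean - segs[k].mean) for k in range(len(segs) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= tol:
            break
        a, b = segs[k], segs[k + 1]
        mean = (a.mean * a.n_probes + b.mean * b.n_probes) / (a.n_probes + b.n_probes)
        segs[k : k + 2] = [
            Segment(
                Region(a.region.chrom, a.region.start, b.region.end),
                a.n_probes + b.n_probes,
                mean,
                thresholds.state(mean),
            )
        ]
    return segs


# ---------------------------------------------------------------------------
# concordance / consensus between two segmenters


def probe_states(
    profile: SegmentedProfile, probes: ProbeSet, thresholds: StateThresholds
) -> np.ndarray:
    """Per-probe 3-level state track implied by a segmentation."""
    out = np.zeros(probes.n_probes, dtype=int)
    for chrom in probes.chroms:
        pos = probes.positions[chrom]
        off = probes.offset(chrom)
        for seg in profile.segments.get(chrom, []):
            lo = int(np.searchsorted(pos, seg.region.start, side="left"))
            hi = int(np.searchsorted(pos, seg.region.end, side="left"))
            out[off + lo : off + hi] = thresholds.state(seg.mean)
    return out


def _breakpoints(profile: SegmentedProfile, probes: ProbeSet) -> list[int]:
    """Internal segment-start probe indices (global flat index space)."""
    bps = []
    for chrom in probes.chroms:
        pos = probes.positions[chrom]
        off = probes.offset(chrom)
        segs = profile.segments.get(chrom, [])
        for seg in segs[1:]:
            bps.append(off + int(np.searchsorted(pos, seg.region.start, side="left")))
    return sorted(bps)


@dataclass
class ConcordanceReport:
    agreement: float
    confusion: np.ndarray  # 3x3, rows = first segmentation, cols = second
    breakpoint_jaccard: float
    n_probes: int = 0

    def __post_init__(self) -> None:
        tr = float(np.trace(self.confusion))
        tot = float(self.confusion.sum())
        if tot and abs(self.agreement - tr / tot) > 1e-12:
            raise ValueError("agreement inconsistent with confusion table")


def probe_state_concordance(
    seg_a: SegmentedProfile,
    seg_b: SegmentedProfile,
    probes: ProbeSet,
    thresholds: StateThresholds = StateThresholds(),
    breakpoint_tol: int = 2,
) -> ConcordanceReport:
    """Probe-state agreement and breakpoint Jaccard between two segmentations."""
    sa = probe_states(seg_a, probes, thresholds)
    sb = probe_states(seg_b, probes, thresholds)
    confusion = np.zeros((3, 3), dtype=int)
    for ia, a in enumerate(_STATES):
        for ib, b in enumerate(_STATES):
            confusion[ia, ib] = int(np.sum((sa == a) & (sb == b)))
    agreement = float(np.mean(sa == sb)) if sa.size else 1.0

    bp_a, bp_b = _breakpoints(seg_a, probes), _breakpoints(seg_b, probes)
    matched = 0
    remaining = list(bp_b)
    for p in bp_a:
        hits = [q for q in remaining if abs(q - p) <= breakpoint_tol]
        if hits:
            remaining.remove(min(hits, key=lambda q: abs(q - p)))
            matched += 1
    union = len(bp_a) + len(bp_b) - matched
    jaccard = matched / union if union else 1.0
    return ConcordanceReport(agreement, confusion, jaccard, sa.size)


def consensus_states(
    seg_a: SegmentedProfile,
    seg_b: SegmentedProfile,
    probes: ProbeSet,
    thresholds: StateThresholds = StateThresholds(),
    policy: str = "agree",
) -> np.ndarray:
    """Per-probe consensus state track.

    ``agree``: keep a non-neutral state only where both segmenters call it;
    ``primary``: keep the first segmenter's states, logging the disagreement
    fraction.
    """
    sa = probe_states(seg_a, probes, thresholds)
    sb = probe_states(seg_b, probes, thresholds)
    if policy == "agree":
        return np.where(sa == sb, sa, NEUTRAL)
    if policy == "primary":
        frac = float(np.mean(sa != sb)) if sa.size else 0.0
        if frac:
            logger.info(
                "consensus(primary) %s: %.1f%% probe-state disagreement",
                seg_a.sample_id, 100 * frac,
            )
        return sa
    raise ValueError(f"unknown consensus policy {policy!r} (use 'agree' or 'primary')")
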