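"""GISTIC-style recurrence scoring.

Each marker gets a per-direction G-score — the cohort-normalised sum of
amplitude exceedances beyond the gain/loss threshold — with significance from
a within-sample marker-permutation null (Monte-Carlo, pooled across markers)
and Benjamini–Hochberg q-values per direction.  Significant peaks are maximal
contiguous sub-threshold marker runs; secondary peaks on a chromosome are
exposed by iterative peel-off of the top peak's carrier segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genome import (
    GAIN,
    LOSS,
    GeneModel,
    GenomeModel,
    ProbeSet,
    Region,
    SegmentedProfile,
    StateThresholds,
    overlap_bp,
    region_length,
)

__all__ = [
    "AmplitudeMatrix",
    "GScoreTrack",
    "Peak",
    "amplitude_matrix",
    "g_score",
    "permutation_null_q",
    "call_peaks",
    "peel_off",
    "classify_focal_broad",
    "gene_alteration_frequency",
    "score_recurrent",
]

DIRECTIONS = ("gain", "loss")


@dataclass
class AmplitudeMatrix:
    """Markers x samples matrix of segment-mean log2 ratios."""

    values: np.ndarray  # (n_markers, n_samples)
    probes: ProbeSet
    sample_ids: list[str]

    def copy(self) -> "AmplitudeMatrix":
        return AmplitudeMatrix(self.values.copy(), self.probes, list(self.sample_ids))


@dataclass
class GScoreTrack:
    direction: str
    g: np.ndarray
    p: np.ndarray
    q: np.ndarray


@dataclass
class Peak:
    direction: str
    region: Region
    marker_span: tuple[int, int]  # half-open flat marker index range
    q_min: float
    q_min_pos: int  # genomic position of the minimal-q marker
    g_max: float
    focal: bool | None = None
    genes: list[str] = field(default_factory=list)
    carriers: list[str] = field(default_factory=list)


def amplitude_matrix(
    profiles: Sequence[SegmentedProfile], probes: ProbeSet
) -> AmplitudeMatrix:
    """Project segment means onto the shared marker grid.

    Entry (m, s) is the mean of sample s's segment covering marker m; a marker
    not covered by any segment violates the tiling contract and raises.
    """
    M = probes.n_probes
    vals = np.full((M, len(profiles)), np.nan)
    for s, prof in enumerate(profiles):
        for chrom in probes.chroms:
            pos = probes.positions[chrom]
            off = probes.offset(chrom)
            for seg in prof.segments.get(chrom, []):
                lo = int(np.searchsorted(pos, seg.region.start, side="left"))
                hi = int(np.searchsorted(pos, seg.region.end, side="left"))
                vals[off + lo : off + hi, s] = seg.mean
        bad = np.isnan(vals[:, s])
        if bad.any():
            m = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"sample {prof.sample_id}: marker index {m} not covered by any segment"
            )
    return AmplitudeMatrix(vals, probes, [p.sample_id for p in profiles])


def _exceedance(values: np.ndarray, thresholds: StateThresholds, direction: str) -> np.ndarray:
    if direction == "loss":
        return np.maximum(0.0, -values - thresholds.loss)
    if direction == "gain":
        return np.maximum(0.0, values - thresholds.gain)
    raise ValueError(f"unknown direction {direction!r}")


def g_score(
    matrix: AmplitudeMatrix,
    thresholds: StateThresholds = StateThresholds(),
    direction: str = "loss",
) -> np.ndarray:
    """Per-marker G-score: mean over samples of the amplitude exceedance.

    For losses ``G_m = (1/N) sum_s max(0, -x_sm - theta_loss)``; gains are
    symmetric with ``+x`` and ``theta_gain``.
    """
    return _exceedance(matrix.values, thresholds, direction).mean(axis=1)


def permutation_null_q(
    matrix: AmplitudeMatrix,
    direction: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    thresholds: StateThresholds = StateThresholds(),
    batch: int = 50,
) -> GScoreTrack:
    """Marker-permutation null and BH q-values for one direction.

    Each sample's marker values are independently permuted ``n_perm`` times;
    all resulting null marker G-scores are pooled, so
    ``p_m = (1 + #{null G >= G_m}) / (1 + n_perm * M)`` — exactly monotone
    non-increasing in G with floor ``1/(1 + n_perm * M)``.  q is BH across
    markers within the direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    E = _exceedance(matrix.values, thresholds, direction)  # (M, N)
    M, N = E.shape
    g_obs = E.mean(axis=1)

    ET = np.ascontiguousarray(E.T)  # (N, M): permute within each sample row
    null_parts = []
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        block = np.broadcast_to(ET, (b, N, M)).copy()
        perm = rng.permuted(block, axis=2)
        null_parts.append(perm.mean(axis=1).ravel())  # b * M null G draws
        done += b
    null_pool = np.sort(np.concatenate(null_parts))
    n_null = null_pool.size
    # #{null >= g} = n_null - searchsorted_left(g)
    count_ge = n_null - np.searchsorted(null_pool, g_obs, side="left")
    p = (1.0 + count_ge) / (1.0 + n_null)
    q = multipletests(p, method="fdr_bh")[1]
    return GScoreTrack(direction, g_obs, p, q)


def call_peaks(
    track: GScoreTrack,
    probes: ProbeSet,
    q_threshold: float = 0.1,
) -> list[Peak]:
    """Maximal contiguous runs of sub-threshold markers, per chromosome.

    Peaks are ordered by minimal q ascending, ties by G at the minimal-q marker
    descending, then genomic order.
    """
    peaks: list[Peak] = []
    for chrom in probes.chroms:
        sl = probes.chrom_slice(chrom)
        q = track.q[sl]
        g = track.g[sl]
        pos = probes.positions[chrom]
        off = probes.offset(chrom)
        below = q < q_threshold
        m = 0
        while m < below.size:
            if not below[m]:
                m += 1
                continue
            m2 = m
            while m2 + 1 < below.size and below[m2 + 1]:
                m2 += 1
            run = slice(m, m2 + 1)
            qr, gr = q[run], g[run]
            # minimal q marker; ties -> highest G, then leftmost
            qmin = qr.min()
            cand = np.flatnonzero(qr == qmin)
            best = cand[np.lexsort((cand, -gr[cand]))[0]]
            peaks.append(
                Peak(
                    direction=track.direction,
                    region=Region(chrom, int(pos[m]), int(pos[m2]) + 1),
                    marker_span=(off + m, off + m2 + 1),
                    q_min=float(qmin),
                    q_min_pos=int(pos[m + int(best)]),
                    g_max=float(gr[int(best)]),
                )
            )
            m = m2 + 1
    peaks.sort(key=lambda p: (p.q_min, -p.g_max, p.region.chrom, p.region.start))
    return peaks


def peel_off(
    matrix: AmplitudeMatrix,
    peak: Peak,
    thresholds: StateThresholds = StateThresholds(),
) -> AmplitudeMatrix:
    """Zero each carrier's full contiguous altered segment overlapping the peak.

    A sample is a carrier when any marker inside the peak exceeds the
    direction's threshold; the whole contiguous exceeding run containing that
    marker (within the chromosome) is reset to 0, so G at the peak strictly
    decreases and iterated peak calling terminates.
    """
    out = matrix.copy()
    chrom = peak.region.chrom
    sl = out.probes.chrom_slice(chrom)
    lo, hi = peak.marker_span
    lo_c, hi_c = lo - sl.start, hi - sl.start  # chromosome-local indices
    sub = out.values[sl, :]
    exceed = _exceedance(sub, thresholds, peak.direction) > 0
    n_chrom = sub.shape[0]
    for s in range(sub.shape[1]):
        col = exceed[:, s]
        if not col[lo_c:hi_c].any():
            continue
        hits = np.flatnonzero(col[lo_c:hi_c]) + lo_c
        for h in hits:
            if not col[h]:
                continue  # already cleared as part of an earlier run
            a = h
            while a > 0 and col[a - 1]:
                a -= 1
            b = h
            while b + 1 < n_chrom and col[b + 1]:
                b += 1
            sub[a : b + 1, s] = 0.0
            col[a : b + 1] = False
    out.values[sl, :] = sub
    return out


def classify_focal_broad(
    region: Region, genome: GenomeModel, broad_fraction: float = 0.5
) -> bool:
    """True when the region is broad: length >= broad_fraction of the containing
    arm (centromere-spanning regions compare against the larger arm)."""
    arm = genome.arm_containing(region)
    return region_length(region) >= broad_fraction * region_length(arm)


def gene_alteration_frequency(
    profiles: Sequence[SegmentedProfile],
    genes: Sequence[GeneModel],
    thresholds: StateThresholds = StateThresholds(),
    direction: str = "loss",
    genome: GenomeModel | None = None,
    min_overlap_fraction: float = 0.0,
    focal_only: bool = False,
) -> dict[str, tuple[int, int, float]]:
    """Per-gene altered-sample counts: a sample counts when any overlapping
    segment's state matches the direction (>=1 bp by default; a minimum overlap
    fraction of the gene is configurable).

    With ``focal_only`` (requires ``genome``), only focal segments count — the
    frequency of the focal event at a locus, excluding whole-arm alterations
    that happen to cover it.
    """
    want = LOSS if direction == "loss" else GAIN
    if focal_only and genome is None:
        raise ValueError("focal_only requires a genome (arm structure)")
    N = len(profiles)
    out: dict[str, tuple[int, int, float]] = {}
    for gene in genes:
        if genome is not None and gene.region.chrom not in genome:
            raise ValueError(f"gene {gene.symbol}: unknown chromosome {gene.region.chrom!r}")
        need = max(1.0, min_overlap_fraction * region_length(gene.region))
        count = 0
        for prof in profiles:
            for seg in prof.segments.get(gene.region.chrom, []):
                if seg.state == want and overlap_bp(seg.region, gene.region) >= need:
                    if focal_only and classify_focal_broad(seg.region, genome):
                        continue
                    count += 1
                    break
        out[gene.symbol] = (count, N, count / N if N else 0.0)
    return out


def gene_sample_states(
    profiles: Sequence[SegmentedProfile],
    genes: Sequence[GeneModel],
    thresholds: StateThresholds = StateThresholds(),
):
    """Sample x gene 5-level state table (-2 deep loss .. +2 amplification).

    A gene's state in a sample is the most extreme 5-level state among
    overlapping segments (ties favour losses, the discovery direction).
    """
    import pandas as pd

    data = {}
    for gene in genes:
        col = []
        for prof in profiles:
            best = 0
            for seg in prof.segments.get(gene.region.chrom, []):
                if overlap_bp(seg.region, gene.region) > 0:
                    s = thresholds.state_5level(seg.mean)
                    if abs(s) > abs(best) or (abs(s) == abs(best) and s < best):
                        best = s
            col.append(best)
        data[gene.symbol] = col
    return pd.DataFrame(data, index=[p.sample_id for p in profiles])


def _annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    genome: GenomeModel | None,
    matrix: AmplitudeMatrix,
    thresholds: StateThresholds,
) -> None:
    peak.genes = [g.symbol for g in genes if overlap_bp(g.region, peak.region) > 0]
    if genome is not None:
        peak.focal = not classify_focal_broad(peak.region, genome)
    lo, hi = peak.marker_span
    ex = _exceedance(matrix.values[lo:hi, :], thresholds, peak.direction)
    carriers = np.flatnonzero(ex.max(axis=0) > 0)
    peak.carriers = [matrix.sample_ids[i] for i in carriers]


def score_recurrent(
    matrix: AmplitudeMatrix,
    directions: Sequence[str] = DIRECTIONS,
    thresholds: StateThresholds = StateThresholds(),
    q_threshold: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    genes: Sequence[GeneModel] = (),
    genome: GenomeModel | None = None,
    max_peel_iterations: int = 10,
) -> tuple[dict[str, GScoreTrack], list[Peak]]:
    """Full recurrence analysis with iterative peel-off.

    Per direction: score + permutation q on the current matrix, record the top
    peak, peel its carriers, repeat until no sub-threshold marker remains or
    the iteration cap is reached.  Returns the first-pass tracks (the reported
    marker tracks) and all recorded peaks (ranked by q_min, then G).
    """
    tracks: dict[str, GScoreTrack] = {}
    all_peaks: list[Peak] = []
    for d_i, direction in enumerate(directions):
        work = matrix
        for it in range(max_peel_iterations):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), d_i, it]))
            track = permutation_null_q(work, direction, n_perm, rng, thresholds)
            if it == 0:
                tracks[direction] = track
            peaks = call_peaks(track, matrix.probes, q_threshold)
            if not peaks:
                break
            top = peaks[0]
            _annotate_peak(top, genes, genome, work, thresholds)
            all_peaks.append(top)
            work = peel_off(work, top, thresholds)
    all_peaks.sort(key=lambda p: (p.q_min, -p.g_max, p.region.chrom, p.region.start))
    return tracks, all_peaks


def ranked_genes(peaks: Sequence[Peak]) -> list[str]:
    """Gene symbols in peak-rank order (q_min ascending, then G), de-duplicated."""
    seen: set[str] = set()
    out: list[str] = []
    for p in sorted(peaks, key=lambda p: (p.q_min, -p.g_max, p.region.chrom, p.region.start)):
        for g in p.genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out
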