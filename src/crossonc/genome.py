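"""Genome models, regions, probe grids, and segment data types.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open ``[start, end)``.  On-disk
formats keep their native conventions: SEG files and intervals printed in
the literature are 1-based inclusive, BED is 0-based half-open.  The
converters in :mod:`crossonc.io` own those translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeModel",
    "Region",
    "ProbeSet",
    "SampleProfile",
    "Segment",
    "SegmentedProfile",
    "GeneModel",
    "StateThresholds",
    "LOSS",
    "NEUTRAL",
    "GAIN",
    "region_length",
    "overlap_bp",
    "region_from_1based",
]

# Per-probe / per-segment copy states.
LOSS = -1
NEUTRAL = 0
GAIN = 1


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start <= end)"
            )

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return self.end - self.start


def region_length(region: Region) -> int:
    """Length of a region in bp (``end - start``)."""
    return region.end - region.start


def overlap_bp(a: Region, b: Region) -> int:
    """Intersection length of two regions; 0 if disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def region_from_1based(chrom: str, start1: int, end1: int) -> Region:
    """Build a Region from 1-based inclusive coordinates (the printed convention).

    ``chr21:17457665-17858164`` as printed becomes ``[17457664, 17858164)``
    internally, with length ``end1 - start1 + 1``.
    """
    return Region(chrom, start1 - 1, end1)


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere {self.centromere} must lie "
                f"strictly inside (0, {self.length})"
            )


class GenomeModel:
    """Ordered chromosome structure for one species.

    Arms derive from the centromere: the p arm is ``[0, centromere)`` and the
    q arm ``[centromere, length)``.
    """

    def __init__(self, species: str, chromosomes: Iterable[tuple[str, int, int]]):
        self.species = species
        self.chromosomes: list[ChromosomeSpec] = [
            ChromosomeSpec(*c) if not isinstance(c, ChromosomeSpec) else c
            for c in chromosomes
        ]
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in genome {species!r}")
        self._by_name = {c.name: c for c in self.chromosomes}

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name

    def chrom(self, name: str) -> ChromosomeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {name!r} for genome {self.species!r}"
            ) from None

    def chrom_length(self, name: str) -> int:
        return self.chrom(name).length

    def arms(self, name: str) -> tuple[Region, Region]:
        """(p-arm, q-arm) regions of a chromosome."""
        c = self.chrom(name)
        return (Region(name, 0, c.centromere), Region(name, c.centromere, c.length))

    def arm_containing(self, region: Region) -> Region:
        """The arm holding a region; for centromere-spanning regions, the larger arm."""
        p, q = self.arms(region.chrom)
        in_p, in_q = overlap_bp(region, p), overlap_bp(region, q)
        if in_p and in_q:
            return p if region_length(p) >= region_length(q) else q
        return p if in_p or region.end <= p.end else q

    def validate_region(self, region: Region) -> None:
        c = self.chrom(region.chrom)
        if region.end > c.length:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {c.length}"
            )


class ProbeSet:
    """The shared marker grid: per-chromosome sorted probe positions and ids.

    Probes are stored in one flat genome order (chromosomes in genome order,
    positions ascending within each chromosome); per-sample value arrays align
    with that flat order.
    """

    def __init__(
        self,
        genome: GenomeModel,
        positions: Mapping[str, Sequence[int]],
        ids: Mapping[str, Sequence[str]],
    ):
        self.genome = genome
        self.positions: dict[str, np.ndarray] = {}
        self.ids: dict[str, list[str]] = {}
        all_ids: list[str] = []
        for chrom in genome.chrom_names:
            if chrom not in positions:
                continue
            pos = np.asarray(positions[chrom], dtype=np.int64)
            pid = list(ids[chrom])
            if len(pos) != len(pid):
                raise ValueError(f"{chrom}: positions/ids length mismatch")
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: probe positions must be strictly increasing")
            self.positions[chrom] = pos
            self.ids[chrom] = pid
            all_ids.extend(pid)
        unknown = set(positions) - set(genome.chrom_names)
        if unknown:
            raise ValueError(
                f"probes on unknown chromosome(s) {sorted(unknown)} "
                f"for genome {genome.species!r}"
            )
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("duplicate probe ids")
        self.chroms = [c for c in genome.chrom_names if c in self.positions]
        self._offsets: dict[str, int] = {}
        off = 0
        for chrom in self.chroms:
            self._offsets[chrom] = off
            off += len(self.positions[chrom])
        self.n_probes = off

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def n_probes_chrom(self, chrom: str) -> int:
        return len(self.positions[chrom])

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + len(self.positions[chrom]))

    def flat_ids(self) -> list[str]:
        out: list[str] = []
        for chrom in self.chroms:
            out.extend(self.ids[chrom])
        return out

    def flat_chroms(self) -> np.ndarray:
        return np.concatenate(
            [np.repeat(c, len(self.positions[c])) for c in self.chroms]
        ) if self.chroms else np.array([], dtype=object)

    def flat_positions(self) -> np.ndarray:
        if not self.chroms:
            return np.array([], dtype=np.int64)
        return np.concatenate([self.positions[c] for c in self.chroms])


@dataclass
class SampleProfile:
    """One sample's probe-level log2 ratios aligned to a ProbeSet (NaN = missing)."""

    sample_id: str
    values: np.ndarray
    probes: ProbeSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.probes.n_probes,):
            raise ValueError(
                f"sample {self.sample_id}: expected {self.probes.n_probes} values, "
                f"got {self.values.shape}"
            )
        if self.probes.n_probes and np.all(np.isnan(self.values)):
            raise ValueError(f"sample {self.sample_id}: all values missing")

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.probes.chrom_slice(chrom)]


@dataclass(frozen=True)
class StateThresholds:
    """Log2-ratio cut-offs for calling gain/loss and high-level events."""

    gain: float = 0.1
    loss: float = 0.1
    high_gain: float = 0.9
    high_loss: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.gain < self.high_gain):
            raise ValueError("need 0 < gain threshold < high-level gain amplitude")
        if not (0 < self.loss < self.high_loss):
            raise ValueError("need 0 < loss threshold < high-level loss amplitude")

    def state(self, mean: float) -> int:
        if mean > self.gain:
            return GAIN
        if mean < -self.loss:
            return LOSS
        return NEUTRAL

    def state_5level(self, mean: float) -> int:
        """Five-level state: -2 deep deletion, -1 loss, 0 neutral, +1 gain, +2 amplification."""
        if mean <= -self.high_loss:
            return -2
        if mean >= self.high_gain:
            return 2
        return self.state(mean)


@dataclass
class Segment:
    """A constant-copy-number stretch: region, probe support, mean log2 ratio, state."""

    region: Region
    n_probes: int
    mean: float
    state: int = NEUTRAL

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must cover at least one probe")


@dataclass
class SegmentedProfile:
    """Ordered segments tiling each covered chromosome of one sample."""

    sample_id: str
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return list(self.segments)

    def validate_tiling(self, probes: ProbeSet) -> None:
        """Check segments are sorted, non-overlapping, and conserve probe counts."""
        for chrom, segs in self.segments.items():
            for a, b in zip(segs, segs[1:]):
                if b.region.start < a.region.end:
                    raise ValueError(
                        f"{self.sample_id}/{chrom}: overlapping segments "
                        f"{a.region} and {b.region}"
                    )
            total = sum(s.n_probes for s in segs)
            if chrom in probes.positions and total != probes.n_probes_chrom(chrom):
                raise ValueError(
                    f"{self.sample_id}/{chrom}: segment probe counts sum to {total}, "
                    f"ProbeSet has {probes.n_probes_chrom(chrom)}"
                )

    def segment_covering(self, chrom: str, pos: int) -> Segment | None:
        for seg in self.segments.get(chrom, []):
            if seg.region.start <= pos < seg.region.end:
                return seg
        return None


@dataclass(frozen=True)
class GeneModel:
    """A gene symbol and its genomic footprint."""

    symbol: str
    region: Region
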