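"""Synthetic two-species aCGH cohorts with a ground-truth synteny map.

The generator emulates the study design this platform targets: a larger
species-A cohort (52 samples on a 22-autosome genome) and a small species-B
cohort (9 samples on a 38-autosome genome) whose genomes are related by a
shuffled/inverted equal-length synteny-block map.  Per sample it plants
whole-arm gains/losses (the chromosomal-instability background) plus focal
events at orthologous driver loci with configurable penetrance, then adds
Gaussian probe noise.  Matched expression matrices carry planted differential
genes driven by deletion status.

Every output is fully determined by (parameters, seed); the truth table
records each planted event so downstream recovery can be audited.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeModel, ProbeSet, Region, SampleProfile, overlap_bp
from .synteny import SyntenyBlock, SyntenyMap, map_region

__all__ = [
    "SimParams",
    "DriverSpec",
    "PlantedDriver",
    "PlantedEvent",
    "TruthTable",
    "SimBundle",
    "default_drivers",
    "landscape_drivers",
    "simulate_synteny_genomes",
    "simulate_cohort",
    "simulate_expression",
    "simulate_two_species",
]


@dataclass(frozen=True)
class DriverSpec:
    """A driver locus in species-A coordinates.

    ``rel_pos`` places the locus start as a fraction of its chromosome length
    so the same spec works at any simulated scale; penetrance 0 in a species
    means the event is never planted there (species-specific drivers).
    """

    symbol: str
    chrom: str
    rel_pos: float
    direction: str  # 'gain' | 'loss'
    penetrance_a: float
    penetrance_b: float
    amplitude: float = 1.0  # magnitude; sign follows direction
    length: int | None = None  # bp; default derives from chromosome length

    def __post_init__(self) -> None:
        for p in (self.penetrance_a, self.penetrance_b):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"driver {self.symbol}: penetrance must be in [0,1]")
        if self.amplitude == 0:
            raise ValueError(f"driver {self.symbol}: amplitude must be nonzero")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"driver {self.symbol}: direction must be gain/loss")


def default_drivers() -> list[DriverSpec]:
    """One shared focal deletion (the DLG2-like locus, penetrance 0.42 / 0.556)
    plus one species-specific deletion driver per species."""
    return [
        DriverSpec("DLG2", "chr5", 0.62, "loss", 0.42, 0.556),
        DriverSpec("TSG_HUMAN", "chr2", 0.55, "loss", 0.40, 0.0),
        DriverSpec("TSG_CANINE", "chr8", 0.55, "loss", 0.0, 0.40),
    ]


def landscape_drivers() -> list[DriverSpec]:
    """A fuller OS-like landscape: six shared driver genes (MYC gain;
    CDKN2A/CDKN2B, RB1, PTEN, DLG2 losses) plus two species-specific loss
    drivers per species, for cross-species overlap exercises."""
    return [
        DriverSpec("MYC", "chr8", 0.65, "gain", 0.50, 0.50),
        DriverSpec("CDKN2A", "chr9", 0.55, "loss", 0.60, 0.65, length=300_000),
        DriverSpec("CDKN2B", "chr9", 0.65, "loss", 0.60, 0.65, length=300_000),
        DriverSpec("RB1", "chr13", 0.55, "loss", 0.55, 0.60),
        DriverSpec("PTEN", "chr10", 0.60, "loss", 0.50, 0.55),
        DriverSpec("DLG2", "chr11", 0.62, "loss", 0.42, 0.556),
        DriverSpec("TSG_HUMAN1", "chr2", 0.55, "loss", 0.45, 0.0),
        DriverSpec("TSG_HUMAN2", "chr4", 0.55, "loss", 0.40, 0.0),
        DriverSpec("TSG_CANINE1", "chr6", 0.55, "loss", 0.0, 0.45),
        DriverSpec("TSG_CANINE2", "chr7", 0.55, "loss", 0.0, 0.40),
    ]


@dataclass(frozen=True)
class SimParams:
    n_samples_a: int = 52
    n_samples_b: int = 9
    n_chrom_a: int = 22
    n_chrom_b: int = 38
    chrom_length: int = 20_000_000
    probes_per_mb: float = 50.0
    sigma: float = 0.15  # per-probe log2 noise sd
    arm_event_prob: float = 0.2  # per (sample, arm); gain/loss equiprobable
    arm_amplitude: float = 0.3
    focal_length_range: tuple[int, int] = (200_000, 2_000_000)
    block_length: int = 5_000_000
    inversion_prob: float = 0.5
    shuffle_blocks: bool = True
    centromere_fraction: float = 0.4
    drivers: tuple[DriverSpec, ...] = tuple(default_drivers())
    n_filler_genes_per_chrom: int = 2
    gene_length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.arm_event_prob <= 1):
            raise ValueError("arm_event_prob must be in [0,1]")
        if self.block_length > self.chrom_length:
            raise ValueError("block length exceeds smallest chromosome")

    def driver_length(self, spec: DriverSpec) -> int:
        if spec.length is not None:
            return spec.length
        lo, hi = self.focal_length_range
        return int(np.clip(self.chrom_length // 10, lo, hi))


@dataclass(frozen=True)
class PlantedDriver:
    """A driver resolved into one species' coordinates."""

    symbol: str
    region: Region
    direction: str
    amplitude: float  # signed
    penetrance: float


@dataclass(frozen=True)
class PlantedEvent:
    sample_id: str
    kind: str  # 'arm' | 'focal'
    region: Region
    amplitude: float
    symbol: str | None = None


@dataclass
class TruthTable:
    """Ground truth for one cohort: every planted event, per-driver carrier
    flags, and the per-probe noise-free mean signal."""

    species: str
    events: list[PlantedEvent] = field(default_factory=list)
    carriers: dict[str, dict[str, bool]] = field(default_factory=dict)
    true_means: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimBundle:
    params: SimParams
    genome_a: GenomeModel
    genome_b: GenomeModel
    synteny: SyntenyMap  # source = B coordinates, target = A coordinates
    probes_a: ProbeSet
    probes_b: ProbeSet
    profiles_a: list[SampleProfile]
    profiles_b: list[SampleProfile]
    truth_a: TruthTable
    truth_b: TruthTable
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    drivers_a: list[PlantedDriver]
    drivers_b: list[PlantedDriver]


def _rng(seed: int, *tags: str | int) -> np.random.Generator:
    ids = [int(seed)] + [
        zlib.crc32(str(t).encode()) & 0x7FFFFFFF if isinstance(t, str) else int(t)
        for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(ids))


# ---------------------------------------------------------------------------
# genomes + synteny map


def simulate_synteny_genomes(
    params: SimParams, seed: int | None = None
) -> tuple[GenomeModel, GenomeModel, SyntenyMap]:
    """Build genome A, partition it into equal-length blocks, permute/invert
    them into genome B, and return the B->A synteny map.

    The blocks tile both genomes exactly once; with ``shuffle_blocks=False``
    and ``inversion_prob=0`` (and equal chromosome counts) the map is the
    identity.
    """
    seed = params.seed if seed is None else seed
    rng = _rng(seed, "synteny")
    L, cen = params.chrom_length, int(params.chrom_length * params.centromere_fraction)
    genome_a = GenomeModel(
        "speciesA", [(f"chr{i+1}", L, cen) for i in range(params.n_chrom_a)]
    )

    # partition A into blocks (last block absorbs any remainder)
    a_blocks: list[Region] = []
    for chrom in genome_a.chrom_names:
        start = 0
        while start < L:
            end = min(start + params.block_length, L)
            if L - end < params.block_length // 2 and end < L:
                end = L  # avoid a tiny trailing sliver
            a_blocks.append(Region(chrom, start, end))
            start = end
    if len(a_blocks) < params.n_chrom_b:
        raise ValueError(
            f"{len(a_blocks)} blocks cannot populate {params.n_chrom_b} chromosomes; "
            "reduce block length"
        )

    order = rng.permutation(len(a_blocks)) if params.shuffle_blocks else np.arange(len(a_blocks))
    inverted = rng.random(len(a_blocks)) < params.inversion_prob

    n_blocks = len(a_blocks)
    base, extra = divmod(n_blocks, params.n_chrom_b)
    sizes = [base + (1 if i < extra else 0) for i in range(params.n_chrom_b)]

    blocks: list[SyntenyBlock] = []
    b_chroms: list[tuple[str, int, int]] = []
    k = 0
    for bi in range(params.n_chrom_b):
        bname = f"chr{bi+1}"
        cursor = 0
        for _ in range(sizes[bi]):
            a_reg = a_blocks[order[k]]
            blen = a_reg.end - a_reg.start
            strand = "-" if inverted[order[k]] else "+"
            blocks.append(
                SyntenyBlock(Region(bname, cursor, cursor + blen), a_reg, strand)
            )
            cursor += blen
            k += 1
        b_chroms.append((bname, cursor, max(1, int(cursor * params.centromere_fraction))))
    genome_b = GenomeModel("speciesB", b_chroms)
    return genome_a, genome_b, SyntenyMap(blocks, genome_b, genome_a)


# ---------------------------------------------------------------------------
# cohort simulation


def _probe_grid(genome: GenomeModel, params: SimParams, tag: str) -> ProbeSet:
    spacing = int(round(1_000_000 / params.probes_per_mb))
    positions, ids = {}, {}
    for c in genome.chromosomes:
        pos = np.arange(spacing // 2, c.length, spacing, dtype=np.int64)
        positions[c.name] = pos
        ids[c.name] = [f"{tag}_{c.name}_{k:06d}" for k in range(pos.size)]
    return ProbeSet(genome, positions, ids)


def resolve_drivers_a(params: SimParams, genome_a: GenomeModel) -> list[PlantedDriver]:
    out = []
    for spec in params.drivers:
        if spec.chrom not in genome_a:
            raise ValueError(f"driver {spec.symbol}: locus chromosome {spec.chrom!r} "
                             f"outside genome {genome_a.species!r}")
        L = genome_a.chrom_length(spec.chrom)
        start = int(spec.rel_pos * L)
        length = params.driver_length(spec)
        if start + length > L:
            raise ValueError(f"driver {spec.symbol}: locus extends past chromosome end")
        region = Region(spec.chrom, start, start + length)
        amp = spec.amplitude if spec.direction == "gain" else -spec.amplitude
        out.append(PlantedDriver(spec.symbol, region, spec.direction, amp, spec.penetrance_a))
    _check_disjoint_drivers(out)
    return out


def map_drivers_to_b(
    drivers_a: Sequence[PlantedDriver],
    params: SimParams,
    smap_b_to_a: SyntenyMap,
) -> list[PlantedDriver]:
    """Lift species-A driver loci into B coordinates (A->B = inverted map).

    Driver loci are placed inside single synteny blocks, so each maps to one
    contiguous B region.
    """
    a_to_b = smap_b_to_a.invert()
    out = []
    for d, spec in zip(drivers_a, params.drivers):
        frags, residue = map_region(d.region, a_to_b)
        if residue or len(frags) != 1:
            raise ValueError(
                f"driver {d.symbol}: locus crosses a synteny-block boundary; "
                "move rel_pos inside a block"
            )
        out.append(PlantedDriver(d.symbol, frags[0][0], d.direction, d.amplitude,
                                 spec.penetrance_b))
    _check_disjoint_drivers(out)
    return out


def _check_disjoint_drivers(drivers: Sequence[PlantedDriver]) -> None:
    for i, a in enumerate(drivers):
        for b in drivers[i + 1 :]:
            if overlap_bp(a.region, b.region) > 0:
                raise ValueError(
                    f"driver loci {a.symbol} and {b.symbol} overlap; planted events "
                    "must be disjoint"
                )


def simulate_cohort(
    genome: GenomeModel,
    params: SimParams,
    drivers: Sequence[PlantedDriver],
    n_samples: int,
    species_tag: str,
    seed: int | None = None,
    sigma: float | None = None,
) -> tuple[ProbeSet, list[SampleProfile], TruthTable]:
    """Simulate one species' cohort on its probe grid.

    Probe value = sum of planted amplitudes covering the probe + N(0, sigma).
    Focal driver events are independent Bernoulli(penetrance) per sample; arm
    events Bernoulli(arm_event_prob) per (sample, arm) with random sign, and
    are suppressed on arms already carrying a focal event so planted events
    never overlap.
    """
    seed = params.seed if seed is None else seed
    sigma = params.sigma if sigma is None else sigma
    probes = _probe_grid(genome, params, species_tag)
    for d in drivers:
        genome.validate_region(d.region)
    truth = TruthTable(species=species_tag)
    for d in drivers:
        truth.carriers[d.symbol] = {}

    profiles = []
    flat_chrom = probes.flat_chroms()
    flat_pos = probes.flat_positions()
    for s in range(n_samples):
        sample_id = f"{species_tag}_{s+1:03d}"
        rng = _rng(seed, "cohort", species_tag, s)
        signal = np.zeros(probes.n_probes)
        blocked_arms: set[tuple[str, int]] = set()

        for d in drivers:
            present = bool(rng.random() < d.penetrance)
            truth.carriers[d.symbol][sample_id] = present
            if not present:
                continue
            mask = (
                (flat_chrom == d.region.chrom)
                & (flat_pos >= d.region.start)
                & (flat_pos < d.region.end)
            )
            signal[mask] += d.amplitude
            truth.events.append(PlantedEvent(sample_id, "focal", d.region, d.amplitude, d.symbol))
            cen = genome.chrom(d.region.chrom).centromere
            blocked_arms.add((d.region.chrom, 0 if d.region.start < cen else 1))

        for c in genome.chromosomes:
            for arm_idx, arm in enumerate(genome.arms(c.name)):
                hit = rng.random() < params.arm_event_prob
                sign = 1.0 if rng.random() < 0.5 else -1.0
                if not hit or (c.name, arm_idx) in blocked_arms:
                    continue
                amp = sign * params.arm_amplitude
                mask = (
                    (flat_chrom == c.name) & (flat_pos >= arm.start) & (flat_pos < arm.end)
                )
                signal[mask] += amp
                truth.events.append(PlantedEvent(sample_id, "arm", arm, amp))

        truth.true_means[sample_id] = signal.copy()
        values = signal + (rng.normal(0.0, sigma, probes.n_probes) if sigma > 0 else 0.0)
        profiles.append(SampleProfile(sample_id, values, probes))
    return probes, profiles, truth


# ---------------------------------------------------------------------------
# genes


def make_genes(
    genome_a: GenomeModel,
    params: SimParams,
    drivers_a: Sequence[PlantedDriver],
) -> list[GeneModel]:
    """Species-A gene annotation: each driver locus hosts exactly one gene (its
    driver symbol), plus filler genes at fixed relative positions away from
    driver loci."""
    genes = [GeneModel(d.symbol, d.region) for d in drivers_a]
    rel = np.linspace(0.1, 0.9, params.n_filler_genes_per_chrom) if params.n_filler_genes_per_chrom else []
    k = 0
    for c in genome_a.chromosomes:
        for r in rel:
            start = int(r * c.length)
            region = Region(c.name, start, min(start + params.gene_length, c.length))
            if any(overlap_bp(region, d.region) > 0 for d in drivers_a):
                continue
            genes.append(GeneModel(f"FILLER_{k:03d}", region))
            k += 1
    return genes


def map_genes_to_b(genes_a: Sequence[GeneModel], smap_b_to_a: SyntenyMap) -> list[GeneModel]:
    """Orthologous gene footprints on genome B (largest fragment if split)."""
    a_to_b = smap_b_to_a.invert()
    out = []
    for g in genes_a:
        frags, _ = map_region(g.region, a_to_b)
        if not frags:
            continue
        best = max(frags, key=lambda fr: fr[0].end - fr[0].start)
        out.append(GeneModel(g.symbol, best[0]))
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    deleted: Sequence[bool],
    n_genes: int,
    n_true_de: int,
    effect: float,
    sigma_e: float = 0.5,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Genes x samples expression matrix with planted differential genes.

    Non-DE genes are Gaussian(mu_g, sigma_e) identically in both groups; each
    true-DE gene is shifted by ±effect (random sign per gene) in the deleted
    group.  ``effect == 0`` yields an empty true-DE set by construction.
    """
    if n_true_de > n_genes:
        raise ValueError("n_true_de cannot exceed n_genes")
    deleted = np.asarray(deleted, dtype=bool)
    if sample_ids is None:
        sample_ids = [f"S{i+1:03d}" for i in range(deleted.size)]
    rng = _rng(seed, "expression")
    gene_ids = [f"G{i+1:05d}" for i in range(n_genes)]
    mu = rng.normal(7.0, 1.0, n_genes)
    X = mu[:, None] + rng.normal(0.0, sigma_e, (n_genes, deleted.size))
    if effect == 0:
        true_idx = np.array([], dtype=int)
    else:
        true_idx = rng.choice(n_genes, size=n_true_de, replace=False)
        signs = np.where(rng.random(n_true_de) < 0.5, -1.0, 1.0)
        X[np.ix_(true_idx, np.flatnonzero(deleted))] += (signs * effect)[:, None]
    df = pd.DataFrame(X, index=gene_ids, columns=list(sample_ids))
    df.index.name = "gene"
    return df, {gene_ids[i] for i in true_idx}


# ---------------------------------------------------------------------------
# two-species convenience wrapper


def simulate_two_species(params: SimParams, seed: int | None = None) -> SimBundle:
    """Generate the full two-species study: genomes + synteny map, both cohorts,
    and orthologous gene annotations."""
    seed = params.seed if seed is None else seed
    genome_a, genome_b, smap = simulate_synteny_genomes(params, seed)
    drivers_a = resolve_drivers_a(params, genome_a)
    drivers_b = map_drivers_to_b(drivers_a, params, smap)
    probes_a, profiles_a, truth_a = simulate_cohort(
        genome_a, params, drivers_a, params.n_samples_a, "A", seed
    )
    probes_b, profiles_b, truth_b = simulate_cohort(
        genome_b, params, drivers_b, params.n_samples_b, "B", seed
    )
    genes_a = make_genes(genome_a, params, drivers_a)
    genes_b = map_genes_to_b(genes_a, smap)
    return SimBundle(
        params, genome_a, genome_b, smap, probes_a, probes_b,
        profiles_a, profiles_b, truth_a, truth_b, genes_a, genes_b,
        drivers_a, drivers_b,
    )


def scaled_params(**overrides) -> SimParams:
    """Desk-scale preset: 5 Mb chromosomes at 10 probes/Mb (50 probes per
    chromosome, ~1,100 species-A markers) with 2.5 Mb synteny blocks.  Keeps
    the study's cohort sizes and penetrances."""
    base = dict(
        chrom_length=5_000_000,
        probes_per_mb=10.0,
        block_length=2_500_000,
        focal_length_range=(200_000, 2_000_000),
    )
    base.update(overrides)
    return SimParams(**base)
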