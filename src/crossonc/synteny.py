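"""Synteny-block coordinate mapping between two genomes and the cross-species
comparison stage: lifting recurrent regions from one species onto the other,
intersecting recurrent regions, ranking shared candidates, and building the
sample x gene status grid.

Blocks are equal-length interval pairs (source on species B, target on species
A) with an orientation; mapping within a block is exactly affine, and on the
minus strand position offsets are mirrored.  Maps with unequal block lengths
are rejected at load time rather than silently rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel, GenomeModel, Region, overlap_bp, region_length
from .io import _open

__all__ = [
    "SyntenyBlock",
    "SyntenyMap",
    "CrossSpeciesCandidate",
    "map_position",
    "map_region",
    "intersect_recurrent",
    "grid_matrix",
    "read_synteny_tsv",
    "write_synteny_tsv",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """An orthologous interval pair; source and target lengths must be equal."""

    source: Region
    target: Region
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if region_length(self.source) != region_length(self.target):
            raise ValueError(
                f"synteny block source {self.source} and target {self.target} have "
                "unequal lengths; pre-split blocks to equal-length pairs "
                "(linear rescaling is not applied)"
            )


def map_position(pos: int, block: SyntenyBlock) -> int:
    """Map a source position through one block (bijective within the block)."""
    if not (block.source.start <= pos < block.source.end):
        raise ValueError(
            f"position {pos} outside block source {block.source.chrom}:"
            f"{block.source.start}-{block.source.end}"
        )
    off = pos - block.source.start
    if block.strand == "+":
        return block.target.start + off
    return block.target.end - 1 - off


class SyntenyMap:
    """An ordered set of synteny blocks linking a source genome to a target genome."""

    def __init__(
        self,
        blocks: Sequence[SyntenyBlock],
        source_genome: GenomeModel | None = None,
        target_genome: GenomeModel | None = None,
    ):
        self.blocks = list(blocks)
        self.source_genome = source_genome
        self.target_genome = target_genome
        if source_genome is not None:
            for b in self.blocks:
                source_genome.validate_region(b.source)
        if target_genome is not None:
            for b in self.blocks:
                target_genome.validate_region(b.target)
        self._check_disjoint([b.source for b in self.blocks], "source")
        self._check_disjoint([b.target for b in self.blocks], "target")
        self._trees: dict[str, IntervalTree] = {}
        for b in self.blocks:
            self._trees.setdefault(b.source.chrom, IntervalTree()).addi(
                b.source.start, b.source.end, b
            )

    @staticmethod
    def _check_disjoint(regions: list[Region], side: str) -> None:
        by_chrom: dict[str, list[Region]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"synteny blocks overlap on {side} {chrom}: {a} vs {b}"
                    )

    def blocks_overlapping(self, region: Region) -> list[SyntenyBlock]:
        tree = self._trees.get(region.chrom)
        if tree is None or region.start == region.end:
            return []
        hits = tree.overlap(region.start, region.end)
        return sorted((h.data for h in hits), key=lambda b: b.source.start)

    def invert(self) -> "SyntenyMap":
        """Swap source/target roles (the map is invertible by construction)."""
        return SyntenyMap(
            [SyntenyBlock(b.target, b.source, b.strand) for b in self.blocks],
            self.target_genome,
            self.source_genome,
        )


def map_region(region: Region, smap: SyntenyMap) -> tuple[list[tuple[Region, Region]], int]:
    """Map a source region through the synteny map.

    Returns ``(fragments, unmapped_bp)`` where each fragment is
    ``(target_region, source_coverage_region)``.  Total mapped length plus the
    unmapped residue always equals the source region length.
    """
    fragments: list[tuple[Region, Region]] = []
    mapped = 0
    for block in smap.blocks_overlapping(region):
        s = max(region.start, block.source.start)
        e = min(region.end, block.source.end)
        if e <= s:
            continue
        src_cov = Region(region.chrom, s, e)
        if block.strand == "+":
            t0 = block.target.start + (s - block.source.start)
            tgt = Region(block.target.chrom, t0, t0 + (e - s))
        else:
            # minus strand mirrors offsets: source [s, e) -> target
            # [end - (e - src.start), end - (s - src.start))
            t_end = block.target.end - (s - block.source.start)
            tgt = Region(block.target.chrom, t_end - (e - s), t_end)
        fragments.append((tgt, src_cov))
        mapped += e - s
    return fragments, region_length(region) - mapped


@dataclass
class CrossSpeciesCandidate:
    """A shared recurrent region, in species-A coordinates."""

    region: Region
    direction: str
    q_a: float
    q_b: float
    genes: list[str] = field(default_factory=list)
    freq_a: tuple[int, int] = (0, 0)  # (altered, N)
    freq_b: tuple[int, int] = (0, 0)
    peak_a: object = None
    peak_b: object = None

    @property
    def worst_q(self) -> float:
        return max(self.q_a, self.q_b)

    @property
    def combined_frequency(self) -> float:
        fa = self.freq_a[0] / self.freq_a[1] if self.freq_a[1] else 0.0
        fb = self.freq_b[0] / self.freq_b[1] if self.freq_b[1] else 0.0
        return fa + fb


def intersect_recurrent(
    peaks_a: Sequence,
    peaks_b_mapped: Sequence[tuple[Region, object]],
    genes_a: Sequence[GeneModel] = (),
    min_overlap_bp: int = 1,
) -> list[CrossSpeciesCandidate]:
    """Intersect species-A peaks with species-B peak fragments already lifted
    into A coordinates.  Directions are matched strictly; candidates are ranked
    by the worse of the two q values (ascending), ties by combined gene
    alteration frequency (descending), then genomic order.

    ``peaks_b_mapped`` holds ``(region_in_A, original_peak_B)`` pairs, one per
    mapped fragment.
    """
    out: list[CrossSpeciesCandidate] = []
    for pa in peaks_a:
        for region_b, pb in peaks_b_mapped:
            if pa.direction != pb.direction:
                continue
            ov = overlap_bp(pa.region, region_b)
            if ov < min_overlap_bp:
                continue
            shared = Region(
                pa.region.chrom,
                max(pa.region.start, region_b.start),
                min(pa.region.end, region_b.end),
            )
            genes = [g.symbol for g in genes_a if overlap_bp(g.region, shared) > 0]
            out.append(
                CrossSpeciesCandidate(
                    region=shared,
                    direction=pa.direction,
                    q_a=pa.q_min,
                    q_b=pb.q_min,
                    genes=genes,
                    peak_a=pa,
                    peak_b=pb,
                )
            )
    out.sort(
        key=lambda c: (
            c.worst_q,
            -c.combined_frequency,
            c.region.chrom,
            c.region.start,
        )
    )
    return out


def grid_matrix(states: pd.DataFrame, anchor_gene: str) -> pd.DataFrame:
    """Order a sample x gene 5-level state table for the status grid.

    Samples sort by the anchor gene's state ascending (deepest loss first),
    then by sample id; genes sort by alteration frequency (fraction of nonzero
    states) descending, ties by column name.
    """
    if anchor_gene not in states.columns:
        raise ValueError(f"anchor gene {anchor_gene!r} not in state table")
    freq = (states != 0).mean(axis=0)
    if (states == 0).all().all():
        gene_order = list(states.columns)
        return states.loc[:, gene_order]
    gene_order = sorted(states.columns, key=lambda g: (-freq[g], str(g)))
    sample_order = sorted(states.index, key=lambda s: (states.at[s, anchor_gene], str(s)))
    return states.loc[sample_order, gene_order]


# ---------------------------------------------------------------------------
# on-disk 7-column synteny TSV (0-based half-open)

SYNTENY_COLUMNS = [
    "src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end", "strand",
]


def write_synteny_tsv(path, smap: SyntenyMap) -> None:
    rows = [
        (b.source.chrom, b.source.start, b.source.end,
         b.target.chrom, b.target.start, b.target.end, b.strand)
        for b in smap.blocks
    ]
    df = pd.DataFrame(rows, columns=SYNTENY_COLUMNS)
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_synteny_tsv(
    path,
    source_genome: GenomeModel | None = None,
    target_genome: GenomeModel | None = None,
) -> SyntenyMap:
    df = pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "dst_chrom": str})
    missing = [c for c in SYNTENY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing synteny column(s) {missing}")
    blocks = [
        SyntenyBlock(
            Region(r.src_chrom, int(r.src_start), int(r.src_end)),
            Region(r.dst_chrom, int(r.dst_start), int(r.dst_end)),
            str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
    return SyntenyMap(blocks, source_genome, target_genome)
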