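"""Readers/writers for the on-disk formats: probe-matrix TSV, SEG, BED, synteny TSV,
expression TSV, labels, and GMT gene sets.  All are gzip-transparent by extension.

Conventions: probe-matrix positions and SEG coordinates are 1-based inclusive on
disk; BED and the synteny TSV are 0-based half-open (matching each format's own
convention).  Internally everything is 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomeModel,
    ProbeSet,
    Region,
    SampleProfile,
    Segment,
    SegmentedProfile,
    StateThresholds,
)

logger = logging.getLogger("crossonc")

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]


def _open(path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# probe-level log2-ratio matrix


def read_probe_matrix(path, genome: GenomeModel) -> tuple[ProbeSet, list[SampleProfile]]:
    """Read a probe matrix TSV (probe_id, chrom, position, one column per sample).

    File positions are 1-based.  Rows are sorted into genome order (a warning is
    logged if the input was unsorted); non-numeric values become missing with a
    warning; duplicate probe ids or unknown chromosomes raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    unknown = set(df["chrom"]) - set(genome.chrom_names)
    if unknown:
        raise ValueError(
            f"{path}: probe(s) on unknown chromosome(s) {sorted(unknown)} "
            f"for genome {genome.species!r}"
        )

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    key = df["chrom"].map(order)
    sorted_idx = np.lexsort((df["position"].to_numpy(), key.to_numpy()))
    if not np.array_equal(sorted_idx, np.arange(len(df))):
        logger.warning("%s: rows not in genome order; sorting", path)
        df = df.iloc[sorted_idx].reset_index(drop=True)

    for col in sample_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        n_bad = int(bad.sum()) if df[col].dtype == object else 0
        if n_bad:
            logger.warning("%s: %d non-numeric value(s) in %s set to missing", path, n_bad, col)
        df[col] = coerced

    positions = {
        chrom: sub["position"].to_numpy(dtype=np.int64) - 1  # 1-based file -> 0-based
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    ids = {chrom: sub["probe_id"].tolist() for chrom, sub in df.groupby("chrom", sort=False)}
    probes = ProbeSet(genome, positions, ids)
    profiles = [
        SampleProfile(col, df[col].to_numpy(dtype=float), probes) for col in sample_cols
    ]
    return probes, profiles


def write_probe_matrix(path, probes: ProbeSet, profiles: Sequence[SampleProfile]) -> None:
    df = pd.DataFrame(
        {
            "probe_id": probes.flat_ids(),
            "chrom": probes.flat_chroms(),
            "position": probes.flat_positions() + 1,  # 0-based -> 1-based
        }
    )
    for p in profiles:
        df[p.sample_id] = p.values
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# SEG


def write_seg(path, profiles: Iterable[SegmentedProfile]) -> None:
    """Write SEG-style TSV; coordinates become 1-based inclusive on disk."""
    rows = []
    for prof in profiles:
        for chrom, segs in prof.segments.items():
            for s in segs:
                rows.append(
                    (prof.sample_id, chrom, s.region.start + 1, s.region.end,
                     s.n_probes, f"{s.mean:.6f}")
                )
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_seg(path, thresholds: StateThresholds | None = None) -> list[SegmentedProfile]:
    """Read a SEG TSV (1-based inclusive) back into SegmentedProfiles.

    Overlapping segments within a sample/chromosome raise, naming the lines.
    States are recomputed from ``thresholds`` (defaults apply if omitted).
    """
    thresholds = thresholds or StateThresholds()
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SEG column(s) {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # 1 header line
    profiles: dict[str, SegmentedProfile] = {}
    for (sample, chrom), sub in df.groupby(["sample", "chrom"], sort=False):
        sub = sub.sort_values("start")
        prev_end, prev_line = None, None
        segs = []
        for row in sub.itertuples(index=False):
            start0, end0 = int(row.start) - 1, int(row.end)
            if prev_end is not None and start0 < prev_end:
                raise ValueError(
                    f"{path}: overlapping segments for {sample}/{chrom} "
                    f"(lines {prev_line} and {row._6})"
                )
            mean = float(row.seg_mean)
            segs.append(
                Segment(Region(chrom, start0, end0), int(row.num_probes), mean,
                        thresholds.state(mean))
            )
            prev_end, prev_line = end0, row._6
        profiles.setdefault(sample, SegmentedProfile(sample)).segments[chrom] = segs
    return list(profiles.values())


# ---------------------------------------------------------------------------
# BED (genes / regions), 0-based half-open


def write_bed(path, items: Iterable[GeneModel | tuple[Region, str]]) -> None:
    with _open(path, "wt") as fh:
        for item in items:
            if isinstance(item, GeneModel):
                r, name = item.region, item.symbol
            else:
                r, name = item
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_genes_bed(path, genome: GenomeModel | None = None) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: need 4 BED columns (chrom,start,end,name)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if genome is not None and chrom not in genome:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene symbol {name!r}")
            seen.add(name)
            genes.append(GeneModel(name, Region(chrom, start, end)))
    return genes


# ---------------------------------------------------------------------------
# expression matrix + labels


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with a `gene` first column."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "gene"
    return df.astype(float)


def write_expression(path, expr: pd.DataFrame) -> None:
    with _open(path, "wt") as fh:
        expr.to_csv(fh, sep="\t", index_label="gene", float_format="%.6f")


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample, status) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (sample, status)")
    return df.set_index(df.columns[0])[df.columns[1]]


# ---------------------------------------------------------------------------
# genome description TSV (chrom, length, centromere)


def write_genome_tsv(path, genome: GenomeModel) -> None:
    with _open(path, "wt") as fh:
        fh.write("chrom\tlength\tcentromere\n")
        for c in genome.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{c.centromere}\n")


def read_genome_tsv(path, species: str | None = None) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "length", "centromere") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing genome column(s) {missing}")
    return GenomeModel(
        species or str(path),
        [(r.chrom, int(r.length), int(r.centromere)) for r in df.itertuples(index=False)],
    )


# ---------------------------------------------------------------------------
# peak tables


def write_peaks_tsv(path, peaks) -> None:
    rows = [
        (p.region.chrom, p.region.start + 1, p.region.end, p.direction,
         f"{p.q_min:.6g}", f"{p.g_max:.6g}", p.q_min_pos + 1,
         {True: "focal", False: "broad", None: "NA"}[p.focal],
         ",".join(p.genes) if p.genes else ".",
         ",".join(p.carriers) if p.carriers else ".")
        for p in peaks
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "q_min", "g_max",
                 "q_min_pos", "focal_broad", "genes", "carriers"],
    )
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_peaks_tsv(path):
    from .recurrence import Peak

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    peaks = []
    for r in df.itertuples(index=False):
        peaks.append(
            Peak(
                direction=str(r.direction),
                region=Region(r.chrom, int(r.start) - 1, int(r.end)),
                marker_span=(0, 0),
                q_min=float(r.q_min),
                q_min_pos=int(r.q_min_pos) - 1,
                g_max=float(r.g_max),
                focal={"focal": True, "broad": False}.get(str(r.focal_broad)),
                genes=[] if r.genes == "." else str(r.genes).split(","),
                carriers=[] if r.carriers == "." else str(r.carriers).split(","),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with _open(path, "rt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
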