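"""Pipeline orchestration: simulate -> segment -> score -> map -> compare -> de.

A single :class:`PipelineConfig` (YAML-loadable) drives the whole run; all
randomness fans out from one global seed via named substreams, so outputs are
a pure function of (config, seed) and stage-by-stage CLI runs reproduce the
single-shot result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .de import differential_genes, ora_fisher
from .genome import GeneModel, GenomeModel, ProbeSet, StateThresholds
from .recurrence import (
    amplitude_matrix,
    gene_alteration_frequency,
    gene_sample_states,
    score_recurrent,
)
from .segmentation import (
    CbsParams,
    cbs_segment,
    penalized_segment,
    probe_state_concordance,
)
from .simulate import SimParams, simulate_expression, simulate_two_species
from .synteny import grid_matrix, intersect_recurrent, map_region, read_synteny_tsv

logger = logging.getLogger("crossonc")


@dataclass
class PipelineConfig:
    outdir: str = "crossonc_out"
    seed: int = 0
    two_species: bool = True
    simulate: bool = True
    sim: SimParams = field(default_factory=SimParams)
    # file-mode inputs (used when simulate=False)
    genome_a: str | None = None
    genome_b: str | None = None
    probe_matrix_a: str | None = None
    probe_matrix_b: str | None = None
    synteny: str | None = None
    genes_a: str | None = None
    genes_b: str | None = None
    expression: str | None = None
    labels: str | None = None
    gmt: str | None = None
    # segmentation
    method: str = "both"  # cbs | penalized | both
    consensus: str = "agree"
    cbs: CbsParams = field(default_factory=CbsParams)
    penalty: float | None = None
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    # recurrence
    n_perm: int = 1000
    q_threshold: float = 0.1
    # DE stage
    de_p_threshold: float = 0.05
    de_q_threshold: float = 0.1
    de_n_genes: int = 2000
    de_n_true: int = 167
    de_effect: float = 4.0
    de_sigma: float = 0.5
    anchor_gene: str = "DLG2"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("sim", SimParams), ("cbs", CbsParams), ("thresholds", StateThresholds)):
            if key in raw and isinstance(raw[key], dict):
                if key == "sim" and "drivers" in raw[key]:
                    from .simulate import DriverSpec

                    raw[key]["drivers"] = tuple(
                        DriverSpec(**d) for d in raw[key]["drivers"]
                    )
                raw[key] = sub(**raw[key])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """All detectable problems, without side effects."""
    problems: list[str] = []
    if not (0 < config.q_threshold < 1):
        problems.append(f"q_threshold={config.q_threshold} not in (0, 1)")
    if not (0 < config.de_p_threshold < 1):
        problems.append(f"de_p_threshold={config.de_p_threshold} not in (0, 1)")
    if not (0 < config.de_q_threshold < 1):
        problems.append(f"de_q_threshold={config.de_q_threshold} not in (0, 1)")
    if config.n_perm < 100:
        problems.append(f"n_perm={config.n_perm} below minimum 100")
    if config.method not in ("cbs", "penalized", "both"):
        problems.append(f"unknown segmentation method {config.method!r}")
    if config.consensus not in ("agree", "primary"):
        problems.append(f"unknown consensus policy {config.consensus!r}")
    if config.simulate:
        if config.sim.n_samples_a < 1 or (config.two_species and config.sim.n_samples_b < 1):
            problems.append("no samples: simulated cohort sizes must be >= 1")
    else:
        needed = [("probe_matrix_a", config.probe_matrix_a), ("genome_a", config.genome_a)]
        if config.two_species:
            needed += [
                ("probe_matrix_b", config.probe_matrix_b),
                ("genome_b", config.genome_b),
                ("synteny", config.synteny),
            ]
        for name, p in needed:
            if p is None:
                problems.append(f"file-mode config missing {name}")
            elif not Path(p).exists():
                problems.append(f"{name}: file not found: {p}")
        if config.two_species and config.synteny and config.genome_a and config.genome_b:
            try:
                ga = cio.read_genome_tsv(config.genome_a, "A")
                gb = cio.read_genome_tsv(config.genome_b, "B")
                read_synteny_tsv(config.synteny, gb, ga)
            except (ValueError, KeyError) as exc:
                problems.append(f"synteny map invalid: {exc}")
    return problems


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _segment_cohort(
    profiles, config: PipelineConfig
) -> tuple[list, list, list]:
    """Segment every sample; returns (primary profiles, secondary, concordance rows)."""
    primary, secondary, rows = [], [], []
    for prof in profiles:
        seg_c = seg_p = None
        if config.method in ("cbs", "both"):
            seg_c = cbs_segment(prof, config.cbs, config.thresholds, config.seed)
        if config.method in ("penalized", "both"):
            seg_p = penalized_segment(prof, config.penalty, config.thresholds)
        primary.append(seg_c if seg_c is not None else seg_p)
        if config.method == "both":
            secondary.append(seg_p)
            rep = probe_state_concordance(seg_c, seg_p, prof.probes, config.thresholds)
            rows.append((prof.sample_id, rep.agreement, rep.breakpoint_jaccard))
    return primary, secondary, rows


def _species_stage(
    tag: str,
    profiles,
    probes: ProbeSet,
    genome: GenomeModel,
    genes: Sequence[GeneModel],
    config: PipelineConfig,
    outdir: Path,
    report: RunReport,
):
    primary, secondary, conc = _segment_cohort(profiles, config)
    cio.write_seg(outdir / f"segments_{tag}.seg", primary)
    if conc:
        pd.DataFrame(conc, columns=["sample", "agreement", "breakpoint_jaccard"]).to_csv(
            outdir / f"concordance_{tag}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    matrix = amplitude_matrix(primary, probes)
    tracks, peaks = score_recurrent(
        matrix,
        thresholds=config.thresholds,
        q_threshold=config.q_threshold,
        n_perm=config.n_perm,
        seed=config.seed,
        genes=genes,
        genome=genome,
    )
    track_df = pd.DataFrame(
        {
            "chrom": probes.flat_chroms(),
            "pos": probes.flat_positions() + 1,
            "g_gain": tracks["gain"].g,
            "q_gain": tracks["gain"].q,
            "g_loss": tracks["loss"].g,
            "q_loss": tracks["loss"].q,
        }
    )
    track_df.to_csv(outdir / f"markers_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
    cio.write_peaks_tsv(outdir / f"peaks_{tag}.tsv", peaks)

    freq_rows = []
    for direction in ("loss", "gain"):
        for sym, (count, N, frac) in gene_alteration_frequency(
            primary, genes, config.thresholds, direction, genome
        ).items():
            freq_rows.append((sym, direction, count, N, frac))
    freq_df = pd.DataFrame(freq_rows, columns=["gene", "direction", "altered", "n", "fraction"])
    freq_df.to_csv(outdir / f"gene_frequency_{tag}.tsv", sep="\t", index=False,
                   float_format="%.6f")

    states = gene_sample_states(primary, genes, config.thresholds)
    anchor = config.anchor_gene if config.anchor_gene in states.columns else states.columns[0]
    grid = grid_matrix(states, anchor)
    grid.to_csv(outdir / f"grid_{tag}.tsv", sep="\t", index_label="sample")

    report.stages[f"segment_{tag}"] = {"samples": len(primary)}
    report.stages[f"score_{tag}"] = {"peaks": len(peaks)}
    return primary, peaks, freq_df


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full cross-species workflow; returns the machine-readable report.

    Raises on any stage error (empty cohort, missing synteny map for a
    two-species run, invalid config).
    """
    t0 = time.time()
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    # ----- inputs
    if config.simulate:
        bundle = simulate_two_species(config.sim, config.seed)
        genome_a, genome_b = bundle.genome_a, bundle.genome_b
        probes_a, profiles_a = bundle.probes_a, bundle.profiles_a
        probes_b, profiles_b = bundle.probes_b, bundle.profiles_b
        genes_a, genes_b = bundle.genes_a, bundle.genes_b
        smap = bundle.synteny
        truth_b = bundle.truth_b
    else:
        genome_a = cio.read_genome_tsv(config.genome_a, "A")
        probes_a, profiles_a = cio.read_probe_matrix(config.probe_matrix_a, genome_a)
        genes_a = cio.read_genes_bed(config.genes_a, genome_a) if config.genes_a else []
        if config.two_species:
            genome_b = cio.read_genome_tsv(config.genome_b, "B")
            probes_b, profiles_b = cio.read_probe_matrix(config.probe_matrix_b, genome_b)
            genes_b = cio.read_genes_bed(config.genes_b, genome_b) if config.genes_b else []
            smap = read_synteny_tsv(config.synteny, genome_b, genome_a)
        truth_b = None
    if not profiles_a or (config.two_species and not profiles_b):
        raise ValueError("no samples")

    # ----- per-species segmentation + recurrence
    primary_a, peaks_a, freq_a = _species_stage(
        "A", profiles_a, probes_a, genome_a, genes_a, config, outdir, report
    )
    if not config.two_species:
        report.wall_time_s = time.time() - t0
        report.to_json(outdir / "report.json")
        return report

    primary_b, peaks_b, freq_b = _species_stage(
        "B", profiles_b, probes_b, genome_b, genes_b, config, outdir, report
    )

    # ----- map species-B peaks onto species A, then intersect
    mapped: list = []
    mapped_rows = []
    for pk in peaks_b:
        frags, residue = map_region(pk.region, smap)
        for region_a, src_cov in frags:
            mapped.append((region_a, pk))
            mapped_rows.append(
                (pk.region.chrom, pk.region.start + 1, pk.region.end, pk.direction,
                 f"{pk.q_min:.6g}", region_a.chrom, region_a.start + 1, region_a.end, residue)
            )
    pd.DataFrame(
        mapped_rows,
        columns=["b_chrom", "b_start", "b_end", "direction", "q_min",
                 "a_chrom", "a_start", "a_end", "unmapped_bp"],
    ).to_csv(outdir / "peaks_B_mapped.tsv", sep="\t", index=False)

    candidates = intersect_recurrent(peaks_a, mapped, genes_a)
    fa = freq_a.set_index(["gene", "direction"])
    fb = freq_b.set_index(["gene", "direction"])
    cand_rows = []
    for c in candidates:
        best_gene, best_fa, best_fb = ".", (0, len(profiles_a)), (0, len(profiles_b))
        for g in c.genes:
            key = (g, c.direction)
            if key in fa.index and key in fb.index:
                ca, na = int(fa.loc[key, "altered"]), int(fa.loc[key, "n"])
                cb, nb = int(fb.loc[key, "altered"]), int(fb.loc[key, "n"])
                if best_gene == "." or ca / na + cb / nb > best_fa[0] / best_fa[1] + best_fb[0] / best_fb[1]:
                    best_gene, best_fa, best_fb = g, (ca, na), (cb, nb)
        c.freq_a, c.freq_b = best_fa, best_fb
        cand_rows.append(
            (c.region.chrom, c.region.start + 1, c.region.end, c.direction,
             f"{c.q_a:.6g}", f"{c.q_b:.6g}",
             ",".join(c.genes) if c.genes else ".",
             f"{best_fa[0]}/{best_fa[1]}", f"{best_fb[0]}/{best_fb[1]}")
        )
    # re-rank now that frequencies are attached (worst-q, then combined frequency)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            candidates[i].worst_q, -candidates[i].combined_frequency,
            candidates[i].region.chrom, candidates[i].region.start,
        ),
    )
    candidates = [candidates[i] for i in order]
    cand_rows = [cand_rows[i] for i in order]
    pd.DataFrame(
        cand_rows,
        columns=["chrom", "start", "end", "direction", "q_a", "q_b",
                 "genes", "freq_a", "freq_b"],
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    report.stages["compare"] = {"candidates": len(candidates)}
    report.candidates = [
        {"region": f"{c.region.chrom}:{c.region.start + 1}-{c.region.end}",
         "direction": c.direction, "genes": c.genes,
         "q_a": c.q_a, "q_b": c.q_b}
        for c in candidates[:20]
    ]

    # ----- DE stage (deletion status of the anchor driver in the B cohort)
    expr = labels = None
    if config.simulate and truth_b is not None and config.anchor_gene in truth_b.carriers:
        carrier = truth_b.carriers[config.anchor_gene]
        deleted = [carrier[p.sample_id] for p in profiles_b]
        if sum(deleted) >= 2 and len(deleted) - sum(deleted) >= 2:
            expr, _true = simulate_expression(
                deleted, config.de_n_genes, config.de_n_true, config.de_effect,
                config.de_sigma, config.seed, [p.sample_id for p in profiles_b],
            )
            labels = pd.Series(
                ["deleted" if d else "wildtype" for d in deleted],
                index=[p.sample_id for p in profiles_b],
            )
        else:
            report.warnings.append(
                "DE stage skipped: fewer than 2 samples in a deletion-status group"
            )
    elif not config.simulate and config.expression and config.labels:
        expr = cio.read_expression(config.expression)
        labels = cio.read_labels(config.labels)
    if expr is not None:
        de = differential_genes(
            expr, labels, config.de_p_threshold, config.de_q_threshold
        )
        de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene",
                  float_format="%.6g")
        report.stages["de"] = {
            "genes": int(len(de)), "significant": int(de["significant"].sum()),
        }
        if config.gmt:
            sets = cio.read_gmt(config.gmt)
            ora = ora_fisher(
                list(de.index[de["significant"]]), sets, list(de.index)
            )
            ora.to_csv(outdir / "ora_results.tsv", sep="\t", float_format="%.6g")
            report.stages["ora"] = {"sets": int(len(ora))}

    report.wall_time_s = time.time() - t0
    report.to_json(outdir / "report.json")
    return report
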