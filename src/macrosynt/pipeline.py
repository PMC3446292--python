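"""End-to-end report bundling: orthology -> synteny -> colinearity
(-> landscape), with every parameter, seed and replicate count echoed into
the JSON report so a run can be reproduced exactly."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_model import (
    GenomeAnnotation,
    read_bed,
    read_blast_tab,
    read_fasta,
    read_gff3,
)
from .landscape import (
    classify_scaffold_completeness,
    cluster_repeats,
    detect_telomere_arrays,
    gc_windows,
    genome_structure_summary,
    summarize_clusters,
)
from .orthology import read_ortholog_tsv, reciprocal_best_hits, write_ortholog_tsv
from .plots import render_dotplot
from .synteny_stats import (
    build_contingency,
    count_cpao,
    cpao_significance,
    scaffold_pair_significance,
    synteny_correlation_significance,
)

logger = logging.getLogger("macrosynt")

__all__ = ["PipelineConfig", "run_pipeline"]


class ConfigurationError(Exception):
    pass


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full comparative run."""

    gff_a: str
    gff_b: str
    blast_ab: str | None = None
    blast_ba: str | None = None
    orthologs: str | None = None
    fasta_a: str | None = None
    fasta_b: str | None = None
    repeats_bed: str | None = None
    repeat_family: str | None = None
    replicates: int = 1000
    seed: int = 0
    top_k: int = 29
    adjacency_mode: str = "all_genes"
    out_dir: str = "macrosynt_out"
    figure_format: str = "svg"
    species_a: str = "genome_A"
    species_b: str = "genome_B"

    def validate(self) -> None:
        missing = [p for p in (self.gff_a, self.gff_b) if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")
        if self.orthologs is None and not (self.blast_ab and self.blast_ba):
            raise ConfigurationError(
                "need either --orthologs or both --blast-ab and --blast-ba"
            )
        for p in (self.blast_ab, self.blast_ba, self.orthologs,
                  self.fasta_a, self.fasta_b, self.repeats_bed):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"missing input file: {p}")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and x != x:
        return None
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full comparison and write a versioned report directory.

    Stages: orthology (RBH unless a precomputed TSV is given) ->
    contingency -> synteny correlation + Z -> per-scaffold-pair Z -> CPAO +
    Z -> dot plot; plus the landscape analyses when sequences/repeats are
    supplied.  Returns the report dict (also written as report.json).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    annot_a = read_gff3(config.gff_a, species_label=config.species_a)
    annot_b = read_gff3(config.gff_b, species_label=config.species_b)
    logger.info(
        "loaded %d + %d genes on %d + %d scaffolds",
        annot_a.n_genes, annot_b.n_genes,
        len(annot_a.scaffolds), len(annot_b.scaffolds),
    )

    if config.orthologs:
        omap = read_ortholog_tsv(config.orthologs)
    else:
        rec_ab = read_blast_tab(config.blast_ab)
        rec_ba = read_blast_tab(config.blast_ba)
        omap = reciprocal_best_hits(rec_ab, rec_ba)
        bits_ab = {(r.query_id, r.subject_id): r.bitscore for r in rec_ab}
        bits_ba = {(r.query_id, r.subject_id): r.bitscore for r in rec_ba}
        write_ortholog_tsv(omap, out / "orthologs.tsv", bits_ab, bits_ba)
    logger.info("ortholog map: %d one-to-one pairs", omap.n)

    cont = build_contingency(omap, annot_a, annot_b)
    pd.DataFrame(cont.counts, index=cont.row_ids, columns=cont.col_ids).to_csv(
        out / "contingency.tsv", sep="\t"
    )

    rho_res = synteny_correlation_significance(
        omap, annot_a, annot_b, config.replicates, config.seed
    )
    zmat = scaffold_pair_significance(
        omap, annot_a, annot_b, config.replicates, config.seed + 1
    )
    rows = []
    for i, rid in enumerate(zmat.row_ids):
        for j, cid in enumerate(zmat.col_ids):
            rows.append(
                {
                    "scaffold_a": rid,
                    "scaffold_b": cid,
                    "observed": int(zmat.observed[i, j]),
                    "null_mean": zmat.null_mean[i, j],
                    "null_sd": zmat.null_sd[i, j],
                    "z": zmat.z[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(out / "scaffold_pair_z.tsv", sep="\t", index=False)

    cpao = cpao_significance(
        omap, annot_a, annot_b, config.replicates, config.seed + 2,
        adjacency_mode=config.adjacency_mode,
    )
    pd.DataFrame(
        cpao.pair_list, columns=["gene_a1", "gene_a2", "gene_b1", "gene_b2"]
    ).to_csv(out / "cpao_pairs.tsv", sep="\t", index=False)

    fig_path = out / f"dotplot.{config.figure_format}"
    render_dotplot(
        omap, annot_a, annot_b, zmat, config.top_k,
        str(fig_path), config.figure_format,
    )

    report = {
        "tool": {"name": "macrosynt", "version": __version__},
        "parameters": {
            "replicates": config.replicates,
            "seed": config.seed,
            "top_k": config.top_k,
            "adjacency_mode": config.adjacency_mode,
            "inputs": {
                "gff_a": config.gff_a, "gff_b": config.gff_b,
                "blast_ab": config.blast_ab, "blast_ba": config.blast_ba,
                "orthologs": config.orthologs, "fasta_a": config.fasta_a,
                "fasta_b": config.fasta_b, "repeats_bed": config.repeats_bed,
            },
        },
        "orthology": {"n_pairs": omap.n},
        "synteny_correlation": {
            "rho": rho_res.rho,
            "null_mean": rho_res.null_mean,
            "null_sd": rho_res.null_sd,
            "z": _jsonable(rho_res.z),
            "replicates": rho_res.replicates,
            "seed": rho_res.seed,
        },
        "scaffold_pairs": {
            "n_significant": int(zmat.significant.sum()),
            "n_undefined": int(zmat.undefined.sum()),
            "replicates": zmat.replicates,
            "seed": zmat.seed,
        },
        "cpao": {
            "n_cpao": cpao.n_cpao,
            "null_mean": cpao.null_mean,
            "null_sd": cpao.null_sd,
            "z": _jsonable(cpao.z),
            "replicates": cpao.replicates,
            "seed": cpao.seed,
        },
    }

    if config.fasta_b or config.fasta_a:
        fasta = config.fasta_b or config.fasta_a
        annot = annot_b if config.fasta_b else annot_a
        seqs, _lengths = read_fasta(fasta)
        track = gc_windows(seqs)
        track.windows.to_csv(out / "gc_track.tsv", sep="\t", index=False)
        telo = detect_telomere_arrays(seqs)
        pd.DataFrame([t.__dict__ for t in telo]).to_csv(
            out / "telomeres.tsv", sep="\t", index=False
        )
        landscape_report = genome_structure_summary(annot, seqs, telo)
        if config.repeats_bed:
            repeats = read_bed(config.repeats_bed)
            clusters = cluster_repeats(repeats, family_filter=config.repeat_family)
            summary = summarize_clusters(clusters, annot, telo, sequences=seqs)
            summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
            landscape_report["n_repeat_clusters"] = len(clusters)
            landscape_report["one_cluster_per_scaffold"] = bool(
                summary["one_cluster"].all()
            )
        report["landscape"] = landscape_report

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(json.dumps(report["parameters"], sort_keys=True) + "\n")
    return report
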