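"""File formats, run configuration, and the end-to-end pipeline runner.

Formats: expression matrices and sample metadata as TSV with explicit
headers, genomic sequences as FASTA (80-column wrap), TSS annotations
as BED6 (0-based half-open), gene sets as two-column TSV.  The runner
chains normalization, differential expression, the status subgroup
contrast, optional VDRE scanning and gene-set enrichment, and cohort
summaries, writing one CSV per stage plus a JSON summary of headline
counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import cohort_stats, diffexpr, enrichment, preprocess
from .matrix import ExpressionMatrix
from .synthetic import SequenceSet, TssAnnotation, load_fixture
from .vdre import ScanParams, build_motif_library, hits_to_frame, scan_upstream

log = logging.getLogger("vdresponse")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, meta_path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus its sample-metadata TSV.

    The expression file has a header of sample ids and gene ids in the
    first column; duplicate gene ids and missing values are rejected.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    if values.isna().any().any():
        raise ValueError(f"missing/ragged values in expression file {path}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, path, meta_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    matrix.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def write_fasta(sequences: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in sequences.records.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tss_bed(sequences: SequenceSet, path) -> None:
    """BED6 of TSS positions (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for ann in sequences.annotations:
            start = ann.tss_position - 1
            fh.write(
                f"{ann.seq_id}\t{start}\t{start + 1}\t{ann.gene_id}\t0\t{ann.strand}\n"
            )


def read_sequences(fasta_path, bed_path) -> SequenceSet:
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    annotations = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 line with {len(fields)} fields: {line!r}")
            seq_id, start, _end, gene_id, _score, strand = fields[:6]
            annotations.append(
                TssAnnotation(gene_id, seq_id, int(start) + 1, strand)
            )
    return SequenceSet(records, annotations)


def read_gene_sets(path) -> pd.DataFrame:
    sets = pd.read_csv(path, sep="\t")
    need = {"set_id", "gene_id"}
    if not need <= set(sets.columns):
        raise ValueError(f"gene-set TSV needs columns {sorted(need)}")
    return sets


# ---------------------------------------------------------------------------
# run configuration and end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths, thresholds, and the seed for an end-to-end run."""

    expression: str | None = None
    metadata: str | None = None
    fasta: str | None = None
    tss: str | None = None
    gene_sets: str | None = None
    outdir: str = "vdresponse_out"
    fdr: float = 0.1
    fc: float = 1.5
    p_subgroup: float = 0.01
    p_pathway: float = 0.05
    max_mismatch: int = 1
    window: tuple[int, int] = (150_000, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1 or not 0 < self.p_subgroup <= 1:
            raise ValueError("fdr and p thresholds must lie in (0, 1]")
        if self.fc < 1:
            raise ValueError("fold-change threshold must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if (self.fasta is None) != (self.tss is None):
            raise ValueError("fasta and tss must be given together")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # re-raise with the stage name attached
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return wrap


def run_all(config: RunConfig) -> dict:
    """Run every configured stage and write per-stage CSV outputs.

    Returns the summary dict (also written as summary.json): counts of
    selected responsive genes with their up/down split, status-contrast
    genes, VDRE-candidate genes, scan hits, enriched sets, and cohort
    serum changes.
    """
    if config.expression is None or config.metadata is None:
        raise ValueError("expression and metadata paths are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": {
        "fdr": config.fdr, "fc": config.fc, "p_subgroup": config.p_subgroup,
        "p_pathway": config.p_pathway, "max_mismatch": config.max_mismatch,
        "window": list(config.window),
    }}
    log.info("thresholds: %s", summary["thresholds"])

    matrix = _stage("read")(read_expression, config.expression, config.metadata)
    norm = _stage("normalize")(preprocess.normalize_gene_level, matrix)
    write_expression(norm, outdir / "normalized.tsv", outdir / "metadata.tsv")

    pca = _stage("pca_qc")(preprocess.pca_qc, norm)
    summary["pca_percent_variance"] = [
        round(float(v), 2) for v in pca.percent_variance[:2]
    ]

    de = _stage("diffexpr")(diffexpr.de_table, norm)
    selection = diffexpr.select_responsive(de, config.fc, config.fdr)
    selection.table.to_csv(outdir / "de.csv", index_label="gene_id")
    summary["n_responsive_selected"] = selection.n_selected
    summary["n_responsive_up"] = len(selection.up)
    summary["n_responsive_down"] = len(selection.down)

    subgroup = _stage("subgroup")(
        diffexpr.baseline_status_diff, norm, config.p_subgroup, config.fc
    )
    subgroup = diffexpr.select_vdre_candidates(subgroup, config.p_subgroup)
    subgroup.to_csv(outdir / "subgroup.csv", index_label="gene_id")
    summary["n_status_selected"] = int(subgroup["selected66"].sum())
    summary["n_vdre_candidate_genes"] = int(subgroup["selected17"].sum())

    if config.fasta is not None:
        seqset = _stage("scan")(read_sequences, config.fasta, config.tss)
        library, motifs = build_motif_library(
            load_fixture("known_vdres"), load_fixture("motif_defs")
        )
        hits = _stage("scan")(
            scan_upstream, seqset, library, motifs, config.window,
            ScanParams(max_mismatch=config.max_mismatch),
        )
        hits_to_frame(hits).to_csv(outdir / "vdre_hits.csv", index=False)
        summary["n_scan_hits"] = len(hits)

    if config.gene_sets is not None:
        sets = _stage("enrich")(read_gene_sets, config.gene_sets)
        population = norm.gene_ids
        enriched = {}
        for direction, genes in (("up", selection.up), ("down", selection.down)):
            table = _stage("enrich")(
                enrichment.enrich_gene_sets, genes, sets, population,
                config.p_pathway,
            )
            table.to_csv(outdir / f"enrichment_{direction}.csv", index=False)
            enriched[direction] = len(table)
        summary["n_enriched_sets_up"] = enriched["up"]
        summary["n_enriched_sets_down"] = enriched["down"]

    meta = norm.meta
    if "serum_25ohd" in meta.columns:
        per_subject = meta.pivot_table(
            index="subject", columns="visit", values="serum_25ohd", aggfunc="first"
        )
        doses = meta.drop_duplicates("subject").set_index("subject")["dose"]
        change = (per_subject["followup"] - per_subject["baseline"]).groupby(doses).mean()
        summary["serum_change_by_dose"] = {
            str(int(d)): round(float(v), 2) for d, v in change.items()
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
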