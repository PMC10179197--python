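"""Pipeline orchestration: catalog -> I/O -> shares -> enrichment -> weighted.

Runs the whole analysis as a configured batch: loads an abundance matrix in
one of the supported dialects, resolves each group's members against the
matrix, applies the half-mean sample filter, computes shares and per-tissue
summaries, tests every member gene x tissue group for enrichment, and
computes weighted totals plus their correlation with the ribosomal-protein
reference set.  Per group it writes a share-matrix TSV, a tissue-summary
TSV and an enrichment TSV (with a significance flag at the configured FDR);
plus weighted-totals and correlation TSVs and a JSON run manifest recording
the seed, permutation count, software version and all exclusion counts.

Per-group failures are logged and do not abort the other groups; the run
fails (nonzero status) only if at least one group failed entirely.
Two runs with identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import catalog as _catalog
from . import expression_io as eio
from . import shares as _shares
from . import weighted as _weighted
from .enrichment import PermutationConfig, run_enrichment

__all__ = ["RunConfig", "RunResult", "run_pipeline", "plot_tissue_shares"]

logger = logging.getLogger("complexshare")

DIALECTS = ("gene_tsv", "gct", "fantom_transcript", "microarray_probe")


@dataclass
class RunConfig:
    """Inputs, dialect and parameters of one pipeline run."""

    expression: Path
    annotation: Path
    out_dir: Path
    dialect: str = "gene_tsv"
    norm_factors: Path | None = None  # fantom_transcript dialect only
    complexes: Path | None = None  # None -> bundled table
    aliases: Path | None = None
    chromosomes: Path | None = None
    ribosomal: Path | None = None
    groups: list[str] | None = None  # None -> all groups
    summary_statistic: str = "median"
    enrichment: PermutationConfig = field(default_factory=PermutationConfig)
    make_plots: bool = False

    def validate(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; choose from {DIALECTS}")
        for label, p in (("expression", self.expression), ("annotation", self.annotation)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.dialect == "fantom_transcript" and self.norm_factors is None:
            raise ValueError("fantom_transcript dialect requires a normalization-factor file")


@dataclass
class RunResult:
    """Exit status, per-group output paths and the run manifest."""

    status: int
    outputs: dict[str, dict[str, Path]]
    manifest: dict


def _safe_name(group: str) -> str:
    return re.sub(r"[^A-Za-z0-9+-]+", "_", group).strip("_")


def _load_matrix(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    notes: dict = {}
    if config.dialect == "gct":
        matrix = eio.read_gct(config.expression)
    elif config.dialect == "gene_tsv":
        matrix = eio.read_expression_tsv(config.expression)
    elif config.dialect == "fantom_transcript":
        table = eio.read_transcript_table(config.expression, config.norm_factors)
        kept = eio.filter_by_norm_factor(table)
        notes["samples_excluded_by_norm_factor"] = len(table.samples) - len(kept.samples)
        matrix = eio.aggregate_transcripts(kept)
    else:  # microarray_probe
        matrix = eio.aggregate_probes(eio.read_probe_table(config.expression), "expression units")
    return matrix, notes


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; see the module docstring for outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix, manifest_notes = _load_matrix(config)
    annotation = eio.read_annotation(config.annotation)
    table = _catalog.load_complex_table(config.complexes)
    registry = _catalog.load_gene_registry(table, config.aliases, config.chromosomes)
    resolution = _catalog.resolve_symbols(table, matrix.index, registry)
    group_names = config.groups if config.groups else list(table.groups)
    unknown = [g for g in group_names if g not in table.groups]
    if unknown:
        raise ValueError(f"requested group(s) not in complex table: {unknown}")

    annotated = [s for s in matrix.columns if s in annotation.index]
    if not annotated:
        raise ValueError("no matrix sample carries a tissue annotation")
    dropped_unannotated = matrix.shape[1] - len(annotated)
    if dropped_unannotated:
        logger.warning("dropping %d unannotated sample(s)", dropped_unannotated)
    matrix = matrix[annotated]

    outputs: dict[str, dict[str, Path]] = {}
    group_manifest: dict[str, dict] = {}
    failures: list[str] = []
    for group in group_names:
        matched, missing = resolution[group]
        try:
            if missing:
                logger.warning("group %s: missing member(s) %s", group, missing)
            totals = _shares.group_totals(matrix, matched, group=group)
            retained = _shares.filter_low_total_samples(totals)
            share_matrix = _shares.compute_shares(matrix, matched, retained, group=group)
            summary = _shares.tissue_summary(
                share_matrix, annotation, statistic=config.summary_statistic
            )
            records = run_enrichment(
                share_matrix, annotation, config.enrichment, group=group
            )
        except Exception as exc:  # noqa: BLE001 - per-group isolation is the contract
            logger.error("group %s failed: %s", group, exc)
            failures.append(group)
            continue
        stem = _safe_name(group)
        paths = {
            "shares": out_dir / f"{stem}.shares.tsv",
            "tissue_summary": out_dir / f"{stem}.tissue_summary.tsv",
            "enrichment": out_dir / f"{stem}.enrichment.tsv",
        }
        share_out = share_matrix.copy()
        share_out.index.name = "gene"
        share_out.to_csv(paths["shares"], sep="\t")
        summary.to_csv(paths["tissue_summary"], sep="\t", index=False)
        records.to_csv(paths["enrichment"], sep="\t", index=False)
        if config.make_plots:
            paths["plot"] = out_dir / f"{stem}.shares.png"
            significant = records[records["significant"]][["gene", "tissue"]]
            plot_tissue_shares(summary, group, paths["plot"], significant=significant)
        outputs[group] = paths
        group_manifest[group] = {
            "members_matched": len(matched),
            "members_missing": missing,
            "samples_input": int(matrix.shape[1]),
            "samples_retained": len(retained),
            "samples_excluded_low_total": int(matrix.shape[1]) - len(retained),
            "tests": int(len(records)),
            "significant": int(records["significant"].sum()) if len(records) else 0,
        }
        logger.info(
            "group %s: %d/%d members, retained %d/%d samples, %d significant tests",
            group, len(matched), len(matched) + len(missing),
            len(retained), matrix.shape[1],
            group_manifest[group]["significant"],
        )

    # weighted totals vs the ribosomal-protein reference
    rp_genes = _catalog.ribosomal_protein_genes(config.ribosomal)
    weighted_rows, corr_rows = [], []
    rp_present = [g for g in rp_genes if g in matrix.index]
    reference = None
    if rp_present:
        reference = _weighted.weighted_total(
            matrix, rp_present, annotation, set_name="ribosomal_proteins"
        )
        weighted_rows.append(reference)
    else:
        logger.warning("no ribosomal-protein gene found in matrix; correlations skipped")
    for group in group_names:
        if group in failures:
            continue
        matched, _ = resolution[group]
        try:
            wt = _weighted.weighted_total(matrix, matched, annotation, set_name=group)
        except ValueError as exc:
            logger.warning("weighted total for group %s skipped: %s", group, exc)
            continue
        weighted_rows.append(wt)
        if reference is not None:
            try:
                r, n, _tissues = _weighted.correlate_with_reference(wt, reference)
            except ValueError as exc:
                logger.warning("correlation for group %s skipped: %s", group, exc)
                continue
            corr_rows.append(
                {"set_a": group, "set_b": "ribosomal_proteins", "n_tissues": n, "pearson_r": r}
            )
    weighted_path = out_dir / "weighted_totals.tsv"
    if weighted_rows:
        weighted_df = pd.concat(
            [wt.rename("weighted_total").to_frame().assign(set_name=wt.name).reset_index()
             for wt in weighted_rows],
            ignore_index=True,
        )[["tissue", "set_name", "weighted_total"]]
    else:
        weighted_df = pd.DataFrame(columns=["tissue", "set_name", "weighted_total"])
    weighted_df.to_csv(weighted_path, sep="\t", index=False)
    corr_path = out_dir / "correlations.tsv"
    pd.DataFrame(corr_rows, columns=["set_a", "set_b", "n_tissues", "pearson_r"]).to_csv(
        corr_path, sep="\t", index=False
    )

    manifest = {
        "version": __version__,
        "dialect": config.dialect,
        "seed": config.enrichment.seed,
        "permutations": config.enrichment.n_permutations,
        "weight_exponent": config.enrichment.weight_exponent,
        "min_set_size": config.enrichment.min_set_size,
        "fdr_threshold": config.enrichment.fdr_threshold,
        "summary_statistic": config.summary_statistic,
        "n_genes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "samples_dropped_unannotated": dropped_unannotated,
        "groups": group_manifest,
        "failed_groups": failures,
        **manifest_notes,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    status = 1 if failures else 0
    return RunResult(status=status, outputs=outputs, manifest=manifest)


def plot_tissue_shares(
    summary: pd.DataFrame,
    group: str,
    out_path: str | Path,
    significant: pd.DataFrame | None = None,
) -> Path | None:
    """Stacked per-tissue share bar chart with significance asterisks.

    ``summary`` is the tidy tissue-summary frame (gene, tissue, summary,
    n_samples); ``significant`` optionally lists (gene, tissue) pairs to
    mark with an asterisk.  Returns the written path, or None (with a
    warning) for an empty summary.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if summary.empty:
        warnings.warn("empty tissue summary; no plot written", UserWarning, stacklevel=2)
        return None
    pivot = summary.pivot(index="tissue", columns="gene", values="summary").fillna(0.0)
    flagged: set[tuple[str, str]] = set()
    if significant is not None and len(significant):
        flagged = {(row.gene, row.tissue) for row in significant.itertuples()}
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(pivot)), 4))
    bottom = pd.Series(0.0, index=pivot.index)
    for gene in pivot.columns:
        heights = pivot[gene]
        bars = ax.bar(pivot.index, heights, bottom=bottom, label=gene)
        for tissue, bar in zip(pivot.index, bars):
            if (gene, tissue) in flagged and bar.get_height() > 0:
                ax.annotate(
                    "*",
                    (bar.get_x() + bar.get_width() / 2, bar.get_y() + bar.get_height() / 2),
                    ha="center", va="center", fontsize=12, fontweight="bold",
                )
        bottom = bottom + heights
    ax.set_ylabel("share of group expression")
    ax.set_title(group)
    ax.tick_params(axis="x", rotation=60)
    ax.legend(fontsize=6, ncols=2, loc="upper right")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
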