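"""End-to-end orchestration of the m6A-pattern workflow.

Stage order: preprocess (merge + normalise) -> consensus clustering on the
regulator panel (m6A clusters) -> single-sample enrichment (immune /
pathway) -> pairwise differential expression between clusters and DEG
intersection -> univariate-Cox prognostic filter -> consensus clustering on
the prognostic signature (gene clusters) -> PCA score fit / stratification /
TMB / combined strata -> survival reports.  Every stage writes its outputs
under the run directory and records a content hash in the run report, so a
re-run with the same config and seed can be verified hash-for-hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ConsensusClustering
from .diffexp import intersect_degs, pairwise_cluster_degs
from .enrichment import score_collection
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    load_registry,
)
from .preprocess import build_meta_cohort
from .scoring import (
    M6AScoreModel,
    build_score_table,
    combine_strata,
    stratify_score,
    tmb_per_sample,
)
from .survival import km_fit, logrank_test, max_sel_cutpoint, prognostic_filter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass
class RunConfig:
    """All inputs and stage parameters for a full pipeline run.

    Inputs may be given as in-memory objects (e.g. from the synthetic
    generator) or file paths loadable by the io module.
    """

    expression: ExpressionMatrix | None = None
    clinical: ClinicalTable | None = None
    mutations: MutationTable | None = None
    gene_sets: GeneSetCollection | None = None
    cohorts: list[ExpressionMatrix] | None = None
    cohort_labels: list[str] | None = None
    outdir: str | Path = "m6a_run"
    k_range: tuple[int, int] = (2, 6)
    reps: int = 1000
    p_item: float = 0.8
    alpha: float = 0.25
    p_cut: float = 0.001
    prognostic_p: float = 0.05
    minprop: float = 0.1
    seed: int = 0
    normalize: bool = True

    def validate(self) -> None:
        if self.expression is None and not self.cohorts:
            raise ValueError("config needs an expression matrix or cohort list")
        if self.clinical is None:
            raise ValueError("config needs a clinical table")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must be in (0, 1]")
        if not 0 < self.minprop < 0.5:
            raise ValueError("minprop must be in (0, 0.5)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class RunReport:
    """Machine-readable record of an executed run."""

    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, stage: str, outputs: dict, **params) -> None:
        self.stages.append({"stage": stage, "params": params, "outputs": outputs})

    def key_outputs(self) -> dict:
        merged: dict = {}
        for s in self.stages:
            merged.update(s["outputs"])
        return merged

    def output_hashes(self) -> dict[str, str]:
        return {
            k: v for s in self.stages for k, v in s["outputs"].items() if k.endswith("_sha256")
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(10).to_csv().encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    return _hash_frame(df)


def run_all(config: RunConfig) -> RunReport:
    """Execute the full workflow; identical config + seed reproduces all hashes."""
    config.validate()
    outdir = Path(config.outdir)
    report = RunReport()
    registry = load_registry()

    # ---- preprocess --------------------------------------------------------
    if config.cohorts:
        meta = build_meta_cohort(config.cohorts, config.cohort_labels or
                                 [f"cohort{i}" for i in range(len(config.cohorts))],
                                 normalize=config.normalize)
        matrix = meta.matrix
    else:
        from .preprocess import quantile_normalize

        matrix = quantile_normalize(config.expression) if config.normalize else config.expression
    clin = config.clinical
    shared = [s for s in matrix.samples if s in clin.samples]
    if len(shared) < len(matrix.samples):
        report.warnings.append(
            f"preprocess: {len(matrix.samples) - len(shared)} samples lack clinical data"
        )
    matrix = ExpressionMatrix(matrix.values[shared], matrix.unit)
    clin_df = clin.data.loc[shared]
    h = _write(matrix.values, outdir / "preprocess" / "matrix.tsv")
    report.add("preprocess", {"n_genes": matrix.shape[0], "n_samples": len(shared),
                              "matrix_sha256": h}, normalize=config.normalize)

    # ---- consensus clustering on the regulator panel ----------------------
    panel = [g for g in registry.symbols if g in matrix.genes]
    if len(panel) < 2:
        raise RuntimeError("consensus_cluster: fewer than 2 regulator genes in the matrix")
    cc = ConsensusClustering(
        matrix.values.loc[panel],
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        reps=config.reps,
        p_item=config.p_item,
        seed=config.seed,
    ).fit()
    m6a_clusters = cc.labels_for().map(lambda i: chr(ord("A") + i - 1)).rename("m6a_cluster")
    if config.k_range[0] == config.k_range[1]:
        report.warnings.append(f"consensus: k forced to {cc.chosen_k} by k_range")
    h = _write(pd.DataFrame({"m6a_cluster": m6a_clusters}), outdir / "clusters" / "m6a_clusters.tsv")
    _write(cc.summary().drop(columns="cluster_sizes"), outdir / "clusters" / "k_diagnostics.tsv")
    report.add("consensus_cluster", {"chosen_k": cc.chosen_k, "n_regulators": len(panel),
                                     "clusters_sha256": h},
               reps=config.reps, p_item=config.p_item, seed=config.seed)

    # ---- enrichment --------------------------------------------------------
    if config.gene_sets is not None:
        scores = score_collection(matrix, config.gene_sets, alpha=config.alpha)
        h = _write(scores.scores, outdir / "enrichment" / "ssgsea.tsv")
        report.add("enrichment", {"n_sets": len(config.gene_sets), "ssgsea_sha256": h},
                   alpha=config.alpha)
    else:
        report.warnings.append("enrichment: no gene sets supplied, stage skipped")

    # ---- differential expression ------------------------------------------
    if cc.chosen_k == 3:
        contrasts = pairwise_cluster_degs(matrix, m6a_clusters, p_cut=config.p_cut)
        overlap = intersect_degs(contrasts)
    else:
        report.warnings.append(
            f"diffexp: chosen_k={cc.chosen_k} != 3; using top-level split contrasts"
        )
        contrasts, overlap = {}, []
        if cc.chosen_k == 2:
            from .diffexp import fit_moderated_t

            res = fit_moderated_t(matrix, m6a_clusters)
            overlap = res.significant(p_cut=config.p_cut)
    degdir = outdir / "degs"
    degdir.mkdir(parents=True, exist_ok=True)
    for name, genes in contrasts.items():
        (degdir / f"{name}.txt").write_text("\n".join(genes) + "\n")
    (degdir / "overlap.txt").write_text("\n".join(overlap) + "\n")
    report.add("diffexp", {"n_overlap_degs": len(overlap),
                           "overlap_sha256": hashlib.sha256("\n".join(overlap).encode()).hexdigest()},
               p_cut=config.p_cut)

    # ---- prognostic filter -------------------------------------------------
    time = clin_df["time"].to_numpy()
    event = clin_df["event"].to_numpy().astype(int)
    if overlap:
        prog = prognostic_filter(matrix, time, event, genes=overlap, p_cut=config.prognostic_p)
        prognostic = prog.index[prog["selected"]].tolist()
        _write(prog, outdir / "survival" / "prognostic_degs.tsv")
    else:
        prognostic = []
        report.warnings.append("survival: empty DEG overlap, prognostic filter skipped")
    report.add("prognostic_filter", {"n_prognostic": len(prognostic)}, p_cut=config.prognostic_p)

    # ---- gene clusters on the prognostic signature ------------------------
    if len(prognostic) >= 2:
        gc = ConsensusClustering(
            matrix.values.loc[prognostic],
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            reps=config.reps,
            p_item=config.p_item,
            seed=config.seed + 1,
        ).fit()
        gene_clusters = gc.labels_for().map(lambda i: chr(ord("a") + i - 1)).rename("gene_cluster")
        h = _write(pd.DataFrame({"gene_cluster": gene_clusters}),
                   outdir / "clusters" / "gene_clusters.tsv")
        report.add("gene_cluster", {"gene_cluster_k": gc.chosen_k, "gene_clusters_sha256": h})
    else:
        gene_clusters = None
        report.warnings.append("gene_cluster: too few prognostic genes, stage skipped")

    # ---- scoring -----------------------------------------------------------
    signature = prognostic if len(prognostic) >= 3 else (overlap if len(overlap) >= 3 else panel)
    fit = M6AScoreModel(matrix, signature).fit()
    scores = fit.scores
    score_group, cut = stratify_score(scores, time, event, minprop=config.minprop)
    chi2, _, p_highlow = logrank_test(time, event, score_group.to_numpy())
    tmb = tmb_group = stratum = None
    strata_p = None
    if config.mutations is not None and len(config.mutations):
        tmb = tmb_per_sample(config.mutations, samples=shared)
        if tmb.nunique() > 1:
            tmb_cut = max_sel_cutpoint(time, event, tmb.to_numpy(), minprop=config.minprop)
            tmb_group = tmb_cut.groups(tmb)
            stratum, strata_global, _ = combine_strata(score_group, tmb_group, time, event)
            strata_p = strata_global[2]
    else:
        report.warnings.append("scoring: no mutation table, TMB stages skipped")
    table = build_score_table(scores, score_group, tmb, tmb_group, stratum)
    h = _write(table, outdir / "score" / "score_table.tsv")
    (outdir / "score" / "model.json").write_text(fit.model.to_json())
    report.add(
        "scoring",
        {
            "n_signature": len(fit.model.genes),
            "cutpoint": cut.cutpoint,
            "n_high": cut.n_high,
            "n_low": cut.n_low,
            "logrank_p_high_vs_low": p_highlow,
            "strata_logrank_p": strata_p,
            "score_table_sha256": h,
        },
        minprop=config.minprop,
    )

    # ---- survival reports --------------------------------------------------
    curves = km_fit(time, event, m6a_clusters.to_numpy())
    cluster_logrank = logrank_test(time, event, m6a_clusters.to_numpy())
    surv_summary = pd.DataFrame(
        {
            g: {
                "n": int((m6a_clusters == g).sum()),
                "five_year_survival": c.survival_at(60.0),
            }
            for g, c in curves.items()
        }
    ).T
    h = _write(surv_summary, outdir / "survival" / "cluster_km.tsv")
    report.add(
        "survival",
        {
            "cluster_logrank_chi2": cluster_logrank[0],
            "cluster_logrank_p": cluster_logrank[2],
            "cluster_km_sha256": h,
        },
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
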