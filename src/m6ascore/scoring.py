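"""The per-sample m6A score and its downstream stratifications.

The score is PCA-based: the prognostic signature genes are z-scored across
samples, the first two principal components of the samples x genes matrix
are extracted, and each sample's score is the sum of its projections onto
components 1 and 2.  Signs of the components are fixed by the
positive-loading-sum convention so scores are reproducible across runs and
linear-algebra backends.

Downstream: high/low score groups via the maximally-selected survival
cutpoint, tumor mutation burden (nonsilent mutation count per sample),
score x TMB strata with 4-group log-rank, mutation / copy-number frequency
summaries, Spearman correlation matrices and rank-based group comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CopyNumberCalls, ExpressionMatrix, MutationTable
from .survival import CutpointResult, logrank_test, max_sel_cutpoint

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "M6AScoreModel",
    "M6AScoreResults",
    "fit_score_model",
    "m6a_score",
    "stratify_score",
    "tmb_per_sample",
    "combine_strata",
    "mutation_frequency",
    "cnv_frequency",
    "correlate",
    "group_compare",
    "build_score_table",
]


@dataclass
class PCAModel:
    """Frozen standardisation + loading vectors for the two retained components."""

    genes: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # shape (n_genes, 2), unit-norm columns
    explained_variance_ratio: np.ndarray  # length 2

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.loadings, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading vectors must be unit-norm")
        if self.explained_variance_ratio[0] < self.explained_variance_ratio[1] - 1e-12:
            raise ValueError("explained variance must be non-increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                "version": 1,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(
            genes=d["genes"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
        )


class M6AScoreModel:
    """PCA score model over a signature gene panel (statsmodels-style).

    ``fit()`` standardises each signature gene across the training samples,
    runs an SVD of the samples x genes matrix and returns results carrying
    the frozen :class:`PCAModel` plus the training scores.
    """

    def __init__(self, x: ExpressionMatrix | pd.DataFrame, signature: list[str]):
        values = x.values if isinstance(x, ExpressionMatrix) else x
        present = [g for g in signature if g in values.index]
        if len(present) < 3:
            raise ValueError(
                f"need >=3 signature genes present in the matrix, got {len(present)}"
            )
        if values.shape[1] < 3:
            raise ValueError("need >=3 samples")
        if len(present) < len(signature):
            logger.info(
                "score model: %d of %d signature genes present", len(present), len(signature)
            )
        self.values = values
        self.signature = present

    def fit(self) -> "M6AScoreResults":
        sub = self.values.loc[self.signature]
        sub = sub[~sub.index.duplicated()]
        means = sub.mean(axis=1).to_numpy()
        sds = sub.std(axis=1, ddof=1).to_numpy()
        keep = sds > 0
        if not keep.all():
            dropped = [g for g, k in zip(sub.index, keep) if not k]
            logger.warning("score model: dropping zero-variance genes %s", dropped)
            sub, means, sds = sub[keep], means[keep], sds[keep]
            if sub.shape[0] < 3:
                raise ValueError("fewer than 3 signature genes with variance")
        z = ((sub.to_numpy().T - means) / sds)  # samples x genes
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        loadings = vt[:2].T.copy()  # genes x 2
        for j in range(2):
            colsum = loadings[:, j].sum()
            if colsum < 0 or (colsum == 0 and loadings[np.nonzero(loadings[:, j])[0][0], j] < 0):
                loadings[:, j] = -loadings[:, j]
        evr = (s**2) / (s**2).sum()
        model = PCAModel(
            genes=sub.index.tolist(),
            means=means,
            sds=sds,
            loadings=loadings,
            explained_variance_ratio=evr[:2],
        )
        return M6AScoreResults(model, m6a_score(model, self.values))


@dataclass
class M6AScoreResults:
    """Fitted score model plus per-sample training scores."""

    model: PCAModel
    scores: pd.Series

    def score(self, x: ExpressionMatrix | pd.DataFrame) -> pd.Series:
        return m6a_score(self.model, x)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_genes": len(self.model.genes),
                "n_samples": len(self.scores),
                "evr_pc1": float(self.model.explained_variance_ratio[0]),
                "evr_pc2": float(self.model.explained_variance_ratio[1]),
                "score_mean": float(self.scores.mean()),
                "score_sd": float(self.scores.std(ddof=1)),
            }
        )


def fit_score_model(x, signature: list[str]) -> PCAModel:
    """Fit and return just the frozen PCA model."""
    return M6AScoreModel(x, signature).fit().model


def m6a_score(model: PCAModel, x: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample score: projection onto PC1 plus projection onto PC2.

    Each projection is sum_g z_gs * loading_g with z the training-frozen
    standardisation, so a sample sitting at the training gene-wise means
    scores exactly 0.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else x
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise KeyError(f"matrix lacks model genes: {missing}")
    z = (values.loc[model.genes].to_numpy().T - model.means) / model.sds
    proj = z @ model.loadings  # samples x 2
    return pd.Series(proj.sum(axis=1), index=values.columns, name="m6a_score")


def stratify_score(
    scores: pd.Series, time, event, minprop: float = 0.1
) -> tuple[pd.Series, CutpointResult]:
    """Split samples into high/low score groups at the maximally-selected cutpoint."""
    cut = max_sel_cutpoint(time, event, scores.to_numpy(), minprop=minprop)
    return cut.groups(scores), cut


def tmb_per_sample(
    mut: MutationTable,
    samples: list[str] | None = None,
    nonsilent_only: bool = True,
    per_mb: float | None = None,
) -> pd.Series:
    """Tumor mutation burden: (nonsilent) mutation count per sample.

    By default the raw count is returned; pass ``per_mb`` (covered megabases)
    to normalise.  Samples requested but absent from the table score 0.
    """
    rec = mut.records
    if nonsilent_only:
        rec = rec[rec["variant_class"] != "silent"]
    counts = rec.groupby("sample_id").size()
    if samples is not None:
        absent = [s for s in samples if s not in counts.index]
        if absent:
            logger.warning("tmb_per_sample: %d samples absent from mutation table, TMB=0", len(absent))
        counts = counts.reindex(samples, fill_value=0)
    counts = counts.astype(float)
    if per_mb is not None:
        counts = counts / per_mb
    counts.name = "tmb"
    return counts


def combine_strata(
    score_group: pd.Series, tmb_group: pd.Series, time, event
) -> tuple[pd.Series, tuple[float, int, float], pd.DataFrame]:
    """Cross score and TMB groups into 4 strata and test survival differences.

    Returns (stratum labels 'H/H'..'L/L', global log-rank (chi2, df, p),
    pairwise log-rank table with BH adjustment).  Empty strata are dropped
    with a warning.
    """
    idx = score_group.index
    if not idx.equals(tmb_group.index):
        raise ValueError("score and TMB groups must cover the same samples")
    stratum = (
        score_group.str.upper().str[0] + "/" + tmb_group.str.upper().str[0]
    ).rename("stratum")
    counts = stratum.value_counts()
    expected = {"H/H", "H/L", "L/H", "L/L"}
    missing = expected - set(counts.index)
    if missing:
        logger.warning("combine_strata: empty strata %s dropped", sorted(missing))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    glob = logrank_test(time, event, stratum.to_numpy())
    levels = sorted(counts.index)
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            mask = stratum.isin([a, b]).to_numpy()
            chi2, _, p = logrank_test(time[mask], event[mask], stratum.to_numpy()[mask])
            rows.append({"a": a, "b": b, "chi2": chi2, "p": p})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return stratum, glob, pairwise


def mutation_frequency(
    mut: MutationTable, genes: list[str], n_samples: int, nonsilent_only: bool = True
) -> pd.DataFrame:
    """Per-gene altered-sample counts and percentages, plus the overall fraction.

    A sample with several hits in one gene counts once for that gene.  The
    overall altered fraction (any listed gene mutated) is stored in
    ``result.attrs['overall_percent']``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rec = mut.records
    if nonsilent_only:
        rec = rec[rec["variant_class"] != "silent"]
    rec = rec[rec["gene_symbol"].isin(set(genes))]
    per_gene = rec.groupby("gene_symbol")["sample_id"].nunique()
    out = pd.DataFrame(
        {
            "count": per_gene.reindex(genes, fill_value=0).astype(int),
        }
    )
    out["percent"] = (out["count"] / n_samples * 100).round(2)
    overall = rec["sample_id"].nunique() / n_samples * 100
    out.attrs["overall_altered"] = int(rec["sample_id"].nunique())
    out.attrs["overall_percent"] = round(float(overall), 2)
    return out


def cnv_frequency(cnv: CopyNumberCalls) -> pd.DataFrame:
    """Per-gene gain and loss frequencies across samples."""
    arr = cnv.calls.to_numpy()
    n = arr.shape[1]
    return pd.DataFrame(
        {
            "gain_freq": (arr > 0).sum(axis=1) / n,
            "loss_freq": (arr < 0).sum(axis=1) / n,
        },
        index=cnv.calls.index,
    )


def correlate(a: pd.DataFrame, b: pd.DataFrame, method: str = "spearman"):
    """Row-by-row Spearman correlation between two matrices over shared samples.

    Returns (rho, p, p_adj) DataFrames of shape (rows of a) x (rows of b).
    Constant rows yield missing correlations with a warning.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    common = a.columns.intersection(b.columns)
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    a, b = a[common], b[common]
    rho = pd.DataFrame(index=a.index, columns=b.index, dtype=float)
    pval = pd.DataFrame(index=a.index, columns=b.index, dtype=float)
    for ia in a.index:
        xa = a.loc[ia].to_numpy()
        for ib in b.index:
            xb = b.loc[ib].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.warning("correlate: constant vector (%s, %s), rho undefined", ia, ib)
                continue
            r, p = stats.spearmanr(xa, xb)
            rho.loc[ia, ib], pval.loc[ia, ib] = r, p
    flat = pval.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    p_adj = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    return rho, pval, p_adj


def group_compare(values, labels, test: str = "wilcoxon") -> tuple[float, float]:
    """Rank-based group comparison with tie correction.

    'wilcoxon' is the two-group rank-sum (Mann-Whitney) test; 'kruskal' the
    k-group Kruskal-Wallis test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon needs exactly 2 groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(stat), float(p)
    if test == "kruskal":
        if len(groups) < 2:
            raise ValueError("kruskal needs >=2 groups")
        stat, p = stats.kruskal(*groups)
        return float(stat), float(p)
    raise ValueError(f"unknown test {test!r}")


def build_score_table(
    scores: pd.Series,
    score_group: pd.Series,
    tmb: pd.Series | None,
    tmb_group: pd.Series | None,
    stratum: pd.Series | None,
) -> pd.DataFrame:
    """Assemble the per-sample score table (score, groups, TMB, stratum)."""
    out = pd.DataFrame({"m6a_score": scores, "score_group": score_group})
    out["tmb"] = tmb if tmb is not None else np.nan
    out["tmb_group"] = tmb_group if tmb_group is not None else "unknown"
    out["stratum"] = stratum if stratum is not None else "unknown"
    return out
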