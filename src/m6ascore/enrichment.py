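"""Rank-based single-sample enrichment (ssGSEA) and over-representation tests.

The ssGSEA engine is the sum-of-differences variant: per sample, genes are
ranked by expression; the score is the sum over all rank positions of the
difference between the weighted in-set ECDF and the unweighted out-set ECDF.
In-set weights are rank_value^alpha with rank_value = n for the highest
expressed gene down to 1 for the lowest, so the score depends only on ranks
and is invariant under strictly monotone per-sample transforms.

The same engine scores immune-cell infiltration signatures, pathway
collections and immune/stromal signatures; pathway activity is computed with
this rank-based engine rather than a kernel-density variant, and the
immune/stromal scores are relative (suited to group comparisons), without
any affine purity transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ssgsea_sample",
    "score_collection",
    "EnrichmentScores",
    "immune_stromal_scores",
    "ora_test",
    "ora_collection",
]


def _rank_order(values: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Order genes by descending expression, ties broken by gene id.

    Returns (ordered gene index positions, rank_value array) where
    rank_value = n at the top position down to 1 at the bottom.
    """
    df = pd.DataFrame({"v": values.to_numpy(), "g": values.index})
    order = df.sort_values(["v", "g"], ascending=[False, True], kind="mergesort").index.to_numpy()
    n = len(values)
    rank_value = np.arange(n, 0, -1)  # n, n-1, ..., 1 along the ordering
    return order, rank_value


def ssgsea_sample(expr_col: pd.Series, gene_set: list[str], alpha: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression column.

    ES = sum over positions of (P_in(pos) - P_out(pos)), with P_in the
    rank-weighted in-set ECDF (weights rank_value^alpha) and P_out the
    unweighted ECDF over out-of-set genes.
    """
    universe = expr_col.index
    in_set = np.asarray(universe.isin(set(gene_set)))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no overlap with the expression universe")
    if n_in == len(universe):
        raise ValueError("gene set equals the whole universe; score undefined")
    order, rank_value = _rank_order(expr_col)
    in_ordered = in_set[order]
    weights = np.where(in_ordered, rank_value.astype(float) ** alpha, 0.0)
    p_in = np.cumsum(weights)
    p_in /= p_in[-1]
    p_out = np.cumsum(~in_ordered) / (len(universe) - n_in)
    assert abs(p_in[-1] - 1.0) < 1e-12 and abs(p_out[-1] - 1.0) < 1e-12
    return float(np.sum(p_in - p_out))


@dataclass
class EnrichmentScores:
    """Set x sample enrichment score matrix."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float

    def groupwise_means(self, groups: pd.Series) -> pd.DataFrame:
        """Mean score per set within each sample group (columns = groups)."""
        return self.scores.T.groupby(groups.reindex(self.scores.columns)).mean().T


def score_collection(
    x: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScores:
    """ssGSEA scores for every set in every sample.

    If ``normalize``, all scores are shifted and scaled by the global
    (min, max) so they land in [0, 1]; a constant score matrix skips
    normalisation with a warning.
    """
    names = sets.names()
    universe = x.values.index
    n = len(universe)
    memberships = {}
    for name in names:
        in_set = np.asarray(universe.isin(set(sets[name])))
        if not in_set.any():
            raise ValueError(f"set {name!r}: no overlap with the expression universe")
        if in_set.all():
            raise ValueError(f"set {name!r}: equals the whole universe; score undefined")
        memberships[name] = in_set
    out = np.empty((len(sets), x.shape[1]))
    # the descending rank order is shared by every set within a sample
    for j, sample in enumerate(x.samples):
        order, rank_value = _rank_order(x.values[sample])
        w_alpha = rank_value.astype(float) ** alpha
        for i, name in enumerate(names):
            in_ordered = memberships[name][order]
            weights = np.where(in_ordered, w_alpha, 0.0)
            p_in = np.cumsum(weights)
            p_in /= p_in[-1]
            p_out = np.cumsum(~in_ordered) / (n - in_ordered.sum())
            out[i, j] = np.sum(p_in - p_out)
    scores = pd.DataFrame(out, index=names, columns=x.samples)
    if normalize:
        lo, hi = float(scores.min().min()), float(scores.max().max())
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
        else:
            logger.warning("score_collection: constant scores, skipping normalisation")
            normalize = False
    return EnrichmentScores(scores, normalized=normalize, alpha=alpha)


def immune_stromal_scores(
    x: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample immune and stromal infiltration scores (higher = more).

    Rank-based single-sample scores of the two signatures; values are
    relative — meaningful for ordering and group comparison, not absolute
    purity estimation.
    """
    collection = GeneSetCollection({"immune": list(immune_set), "stromal": list(stromal_set)})
    scores = score_collection(x, collection, alpha=alpha, normalize=False).scores
    return pd.DataFrame(
        {"immune_score": scores.loc["immune"], "stromal_score": scores.loc["stromal"]}
    )


def ora_test(hits: list[str], gene_set: list[str], universe: list[str]) -> tuple[float, float]:
    """One-sided hypergeometric over-representation test.

    Returns (odds ratio, p-value) for observing at least the given overlap
    between ``hits`` and ``gene_set`` inside ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    h = set(hits) & uni
    s = set(gene_set) & uni
    overlap = len(h & s)
    N, K, n = len(uni), len(s), len(h)
    p = float(hypergeom.sf(overlap - 1, N, K, n))
    a, b = overlap, len(h) - overlap
    c, d = len(s) - overlap, N - len(h) - len(s) + overlap
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return odds, min(p, 1.0)


def ora_collection(
    hits: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """ORA across a collection with Benjamini-Hochberg adjustment."""
    rows = []
    for name in sets.names():
        odds, p = ora_test(hits, sets[name], universe)
        rows.append({"set": name, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
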