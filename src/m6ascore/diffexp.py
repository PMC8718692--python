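"""Empirical-Bayes moderated two-group differential expression.

Per gene, an ordinary two-sample linear model gives a mean difference and a
pooled residual variance s2_g on d_g degrees of freedom.  The gene variances
are then shrunk toward a common prior: assuming s2_g | sigma2_g follows a
scaled chi-square and sigma2_g an inverse-chi-square prior with d0 degrees
of freedom and scale s0^2, the posterior variance is

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t = diff / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a
t-distribution on d0 + d_g degrees of freedom.  The hyperparameters (d0,
s0^2) are estimated by the method of moments on log s2_g using the digamma /
trigamma closed forms (Smyth 2004): with z_g = log s2_g and
e_g = z_g - digamma(d_g/2) + log(d_g/2),

    trigamma(d0/2) = var(e) - mean(trigamma(d_g/2))
    log s0^2       = mean(e) + digamma(d0/2) - log(d0/2)

trigamma is inverted by Newton iteration; a non-positive right-hand side
means no excess dispersion beyond sampling noise and yields d0 = inf (full
shrinkage to s0^2).  Zero-variance genes are excluded from the moment fit
(log 0 is undefined) and receive the prior-shrunk posterior variance
d0*s0^2/(d0+d_g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedTTest",
    "DEResults",
    "fit_moderated_t",
    "pairwise_cluster_degs",
    "intersect_degs",
]


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on the inverse scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    # starting value from the asymptotic expansion trigamma(x) ~ 1/x + 1/(2x^2)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from gene variances on common df."""
    positive = s2 > 0
    if positive.sum() < 2:
        raise ValueError("need at least two genes with positive variance to fit the prior")
    z = np.log(s2[positive])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    rhs = e_var - _trigamma(df / 2.0)
    if rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class DEResults:
    """Per-gene moderated-t results for one two-group contrast."""

    table: pd.DataFrame  # diff, s2, s2_post, t, p, p_adj per gene
    contrast: str
    d0: float
    s0_sq: float
    df_residual: float

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual

    def significant(self, p_cut: float = 0.001, adjusted: bool = False) -> list[str]:
        col = "p_adj" if adjusted else "p"
        return self.table.index[self.table[col] < p_cut].tolist()

    def summary(self, n: int = 10) -> pd.DataFrame:
        """Top genes by p-value with the shrinkage hyperparameters attached."""
        out = self.table.sort_values("p").head(n).copy()
        out.attrs["d0"] = self.d0
        out.attrs["s0_sq"] = self.s0_sq
        out.attrs["contrast"] = self.contrast
        return out


class ModeratedTTest:
    """Two-group moderated-t model over a log-scale expression matrix.

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary two-sample t-test, inf forces every posterior variance to s0^2.
    """

    def __init__(
        self,
        x: ExpressionMatrix | pd.DataFrame,
        groups: pd.Series,
        contrast: str = "",
    ):
        values = x.values if isinstance(x, ExpressionMatrix) else x
        groups = groups.reindex(values.columns)
        if groups.isna().any():
            raise ValueError("groups must label every sample")
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 group levels, got {levels}")
        n_per = groups.value_counts()
        if (n_per < 2).any():
            raise ValueError("each group needs at least 2 samples")
        self.values = values
        self.groups = groups
        self.levels = levels
        self.contrast = contrast or f"{levels[0]}-vs-{levels[1]}"

    def fit(self, d0_override: float | None = None) -> DEResults:
        a_mask = (self.groups == self.levels[0]).to_numpy()
        b_mask = ~a_mask
        arr = self.values.to_numpy(dtype=float)
        n1, n2 = int(a_mask.sum()), int(b_mask.sum())
        mean1 = arr[:, a_mask].mean(axis=1)
        mean2 = arr[:, b_mask].mean(axis=1)
        diff = mean1 - mean2
        ss = arr[:, a_mask].var(axis=1, ddof=1) * (n1 - 1) + arr[:, b_mask].var(
            axis=1, ddof=1
        ) * (n2 - 1)
        df_res = n1 + n2 - 2
        s2 = ss / df_res
        if d0_override is not None and d0_override == 0:
            d0, s0_sq = 0.0, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
        else:
            d0, s0_sq = estimate_prior(s2, df_res)
            if d0_override is not None:
                d0 = float(d0_override)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
            df_total = d0 + df_res
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, diff / se, 0.0)
        if np.isinf(df_total):
            from scipy.stats import norm

            p = 2.0 * norm.sf(np.abs(tstat))
        else:
            p = 2.0 * t_dist.sf(np.abs(tstat), df_total)
        p_adj = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {
                "diff": diff,
                "s2": s2,
                "s2_post": s2_post,
                "t": tstat,
                "p": p,
                "p_adj": p_adj,
            },
            index=self.values.index,
        )
        return DEResults(table, self.contrast, d0=d0, s0_sq=s0_sq, df_residual=df_res)


def fit_moderated_t(
    x: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series,
    d0_override: float | None = None,
    contrast: str = "",
) -> DEResults:
    """Convenience wrapper: build the model and fit in one call."""
    return ModeratedTTest(x, groups, contrast=contrast).fit(d0_override=d0_override)


def pairwise_cluster_degs(
    x: ExpressionMatrix | pd.DataFrame,
    cluster_labels: pd.Series,
    p_cut: float = 0.001,
    adjusted: bool = False,
) -> dict[str, list[str]]:
    """DEG lists for every pairwise contrast between three clusters.

    Genes pass at raw p < ``p_cut`` by default (the conventional candidate
    filter); set ``adjusted=True`` to filter on BH-adjusted p instead.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else x
    cluster_labels = cluster_labels.reindex(values.columns)
    levels = sorted(cluster_labels.unique())
    if len(levels) != 3:
        raise ValueError(f"expected exactly 3 clusters, got {levels}")
    out: dict[str, list[str]] = {}
    for a, b in combinations(levels, 2):
        mask = cluster_labels.isin([a, b])
        sub = values.loc[:, mask.to_numpy()]
        res = fit_moderated_t(sub, cluster_labels[mask], contrast=f"{a}-vs-{b}")
        out[res.contrast] = res.significant(p_cut=p_cut, adjusted=adjusted)
    return out


def intersect_degs(contrast_sets: dict[str, list[str]]) -> list[str]:
    """Genes present in every contrast's DEG list, sorted lexicographically."""
    if len(contrast_sets) < 2:
        raise ValueError("need at least 2 contrast sets")
    sets = [set(v) for v in contrast_sets.values()]
    common = set.intersection(*sets)
    if not common:
        logger.warning("intersect_degs: empty intersection")
    return sorted(common)
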