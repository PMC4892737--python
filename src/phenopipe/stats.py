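"""Downstream statistics for digital traits.

The standard phenomics analysis chain after trait extraction:

* **adjusted means** — per-genotype means corrected for experiment
  (batch) effects by an additive two-factor least-squares fit, used when an
  experiment is replicated across growth-chamber runs;
* **Pearson correlation** — e.g. digital shoot area against destructive
  biomass measurements;
* **complete-linkage hierarchical clustering** with Euclidean distance —
  e.g. grouping genotypes by raw image moments into architectural classes;
* **one-way ANOVA** — testing whether a trait differs across those classes.

Genotype is fitted as a fixed effect here; trait matrices are clustered at
their native scale by default (a ``standardize`` flag is provided because
raw moments of different orders live on wildly different scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import StatsError

__all__ = [
    "adjusted_means",
    "pearson",
    "Dendrogram",
    "cluster_complete_linkage",
    "AnovaResult",
    "one_way_anova",
]


def adjusted_means(
    table: pd.DataFrame,
    trait: str,
    genotype_col: str = "genotype",
    experiment_col: str = "experiment",
) -> pd.Series:
    """Experiment-adjusted per-genotype means of one trait.

    Fits the additive fixed-effects model ``trait ~ genotype + experiment``
    (no interaction) by least squares and evaluates each genotype's
    prediction at the unweighted average of the experiment effects.  On a
    balanced design, or with a single experiment, this collapses to the
    plain per-genotype arithmetic mean.

    Genotypes with no non-missing observation are excluded; their names are
    available on the result as ``result.attrs["excluded"]``.
    """
    df = table[[genotype_col, experiment_col, trait]].copy()
    df[trait] = pd.to_numeric(df[trait], errors="coerce")
    all_genotypes = pd.unique(df[genotype_col])
    df = df.dropna(subset=[trait])
    present = pd.unique(df[genotype_col])
    excluded = sorted(set(map(str, all_genotypes)) - set(map(str, present)))
    if len(present) == 0:
        raise StatsError(f"no non-missing observations for trait {trait!r}")

    experiments = sorted(pd.unique(df[experiment_col].astype(str)))
    genotypes = sorted(pd.unique(df[genotype_col].astype(str)))
    if len(experiments) == 1:
        result = df.groupby(df[genotype_col].astype(str))[trait].mean()
        result = result.reindex(genotypes)
    else:
        # full-rank dummy coding: intercept + genotype (drop first) + experiment
        # (drop first); adjusted mean g = intercept + b_g + mean_e(b_e)
        g_idx = {g: i for i, g in enumerate(genotypes)}
        e_idx = {e: i for i, e in enumerate(experiments)}
        n = len(df)
        X = np.zeros((n, 1 + len(genotypes) - 1 + len(experiments) - 1))
        X[:, 0] = 1.0
        g_codes = df[genotype_col].astype(str).map(g_idx).to_numpy()
        e_codes = df[experiment_col].astype(str).map(e_idx).to_numpy()
        for row, (g, e) in enumerate(zip(g_codes, e_codes)):
            if g > 0:
                X[row, g] = 1.0
            if e > 0:
                X[row, len(genotypes) - 1 + e] = 1.0
        y = df[trait].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept = beta[0]
        g_eff = np.concatenate([[0.0], beta[1 : len(genotypes)]])
        e_eff = np.concatenate([[0.0], beta[len(genotypes) :]])
        values = intercept + g_eff + e_eff.mean()
        result = pd.Series(values, index=genotypes, name=trait)
    result.index.name = genotype_col
    result.attrs["excluded"] = excluded
    return result


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError(f"x and y must be equal-length 1-D, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise StatsError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined: an input has zero variance")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class Dendrogram:
    """Agglomerative merge history in SciPy linkage form plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialise as a Newick tree; branch lengths are merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            return (
                f"({node(a)}:{h - heights[a]:g},{node(b)}:{h - heights[b]:g})"
            )

        for k, (a, b, h, _) in enumerate(self.linkage):
            heights[n + k] = h
        return node(n + len(self.linkage) - 1) + ";"


def cluster_complete_linkage(
    matrix: Union[np.ndarray, pd.DataFrame],
    cut: Optional[Union[float, int]] = None,
    *,
    k: Optional[int] = None,
    height: Optional[float] = None,
    standardize: bool = False,
    labels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, Dendrogram]:
    """Complete-linkage agglomerative clustering with Euclidean distance.

    ``matrix`` is observations x traits.  Cut the dendrogram either into
    ``k`` groups or at a Euclidean distance ``height``; ``cut`` is a
    convenience alias (int → k, float → height).  Returns integer labels
    (1-based, as assigned by the cut) and the :class:`Dendrogram`.

    Traits are used at their native scale unless ``standardize`` is set
    (z-score per column).  Missing values are rejected — impute or drop
    upstream.  Merge heights are non-decreasing (complete linkage is
    monotone); distance ties are broken deterministically by observation
    order.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise StatsError(f"need at least 2 observations, got {X.shape[0]}")
    if np.isnan(X).any():
        raise StatsError(
            "matrix contains missing values; impute or drop them before clustering"
        )
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]

    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    dendro = Dendrogram(linkage=Z, labels=list(labels))

    if isinstance(cut, bool):
        raise StatsError("cut must be an int (k) or float (height)")
    if cut is not None:
        if isinstance(cut, (int, np.integer)):
            k = int(cut)
        else:
            height = float(cut)
    if k is not None:
        assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        assignments = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        assignments = np.ones(X.shape[0], dtype=int)
    return assignments, dendro


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict
    df_between: int
    df_within: int


def one_way_anova(groups: Sequence, values: Sequence[float]) -> AnovaResult:
    """One-way fixed-effects ANOVA across the label groups.

    Standard between/within sum-of-squares decomposition; p-value from the
    F distribution on (k−1, N−k) degrees of freedom.  Every group must have
    at least two observations.
    """
    groups = np.asarray([str(g) for g in groups])
    values = np.asarray(values, dtype=float)
    if groups.shape != values.shape:
        raise StatsError("groups and values must have equal length")
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise StatsError(f"need at least 2 groups, got {len(names)}")
    samples = {g: values[groups == g] for g in names}
    small = [g for g, v in samples.items() if v.size < 2]
    if small:
        raise StatsError(f"group(s) with fewer than 2 observations: {small}")

    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in samples.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    df_b = len(names) - 1
    df_w = values.size - len(names)
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f_statistic=float(f),
        p_value=p,
        group_means={g: float(v.mean()) for g, v in samples.items()},
        df_between=df_b,
        df_within=df_w,
    )
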