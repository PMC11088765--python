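"""Per-sample signature scoring and cohort-level differential abundance.

Expression cohorts get a rank-based single-sample gene-set score (a weighted
Kolmogorov-Smirnov random walk over within-sample gene ranks, in the style of
GSVA); protein cohorts get the mean NPX of signature proteins after
missingness QC and KNN imputation.  Scores are dichotomized at the cohort
mean into high/low levels for Kaplan-Meier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .synthetic_data import Cohort

__all__ = [
    "ScoreVector",
    "qc_and_impute",
    "gene_set_score",
    "protein_score",
    "dichotomize",
    "differential_abundance",
]


@dataclass
class ScoreVector:
    """Per-sample scores with the mean cutoff and high/low levels attached."""

    scores: pd.Series
    cutoff: float
    levels: pd.Series  # "high" iff score > cutoff else "low"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "level": self.levels, "cutoff": self.cutoff}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


def dichotomize(scores: pd.Series) -> ScoreVector:
    """Split at the mean of the same vector: high iff score > mean."""
    cutoff = float(scores.mean())
    levels = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="level"
    )
    return ScoreVector(scores=scores, cutoff=cutoff, levels=levels)


def qc_and_impute(proteins: Cohort, max_missing: float = 0.20, k: int = 10) -> Cohort:
    """Drop high-missingness proteins, then KNN-impute the remaining gaps.

    Features missing in strictly more than ``max_missing`` of samples are
    removed (a feature at exactly the threshold is kept).  Remaining gaps are
    filled with the mean of the ``k`` nearest samples under Euclidean distance
    over mutually observed features; observed values are untouched.
    """
    vals = proteins.values
    if vals.isna().all(axis=1).any():
        bad = vals.index[vals.isna().all(axis=1)].tolist()
        raise ValueError(f"samples with all features missing: {bad}")
    frac = vals.isna().mean(axis=0)
    kept = vals.loc[:, frac <= max_missing]
    if kept.isna().to_numpy().any():
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        filled = imputer.fit_transform(kept.to_numpy(dtype=float))
        kept = pd.DataFrame(filled, index=kept.index, columns=kept.columns)
    return Cohort(kept.copy(), proteins.samples.copy())


def _sample_walk_score(ecdf_row: pd.Series, hits: set[str]) -> float:
    """Weighted KS random-walk score for one sample (weight exponent 1)."""
    order = sorted(ecdf_row.index, key=lambda g: (-ecdf_row[g], g))
    w = ecdf_row.loc[order].to_numpy(dtype=float)
    is_hit = np.fromiter((g in hits for g in order), dtype=bool, count=len(order))
    w_hit_total = w[is_hit].sum()
    n_miss = (~is_hit).sum()
    step = np.where(is_hit, w / w_hit_total, -1.0 / n_miss)
    walk = np.cumsum(step)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def gene_set_score(expr: Cohort, signature) -> ScoreVector:
    """Rank-based single-sample gene-set score in [-1, 1].

    Per feature, expression is transformed across samples to empirical-CDF
    values; per sample, features are ranked by that value (ties broken by
    symbol) and a weighted Kolmogorov-Smirnov random walk is taken over the
    list with the signature as the hit set (hit steps proportional to the
    ecdf value, weight exponent 1).  The score is the signed sum of the walk's
    maximum positive and maximum negative deviations.
    """
    vals = expr.values
    if vals.shape[0] < 3:
        raise ValueError("need at least three samples")
    present = [g for g in signature if g in vals.columns]
    missing = [g for g in signature if g not in vals.columns]
    if len(present) < 2:
        raise ValueError(
            f"fewer than two signature genes present; missing: {missing}"
        )
    if len(present) >= vals.shape[1]:
        raise ValueError("signature covers every feature; walk undefined")
    ecdf = vals.apply(lambda col: rankdata(col, method="average") / len(col), axis=0)
    hits = set(present)
    scores = pd.Series(
        [_sample_walk_score(ecdf.loc[s], hits) for s in ecdf.index],
        index=ecdf.index,
        name="score",
    )
    return dichotomize(scores)


def protein_score(proteins: Cohort, signature) -> ScoreVector:
    """Mean observed NPX of signature proteins per sample.

    Missing values are excluded pairwise (mean of the observed signature
    proteins in each sample).
    """
    present = [g for g in signature if g in proteins.values.columns]
    if not present:
        raise ValueError("no signature proteins among cohort features")
    scores = proteins.values[present].mean(axis=1, skipna=True).rename("score")
    return dichotomize(scores)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when untied, else tie-corrected
    normal approximation without continuity correction (so that identical
    group distributions give p = 1 exactly)."""
    if len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        return float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    return float(
        mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    )


def differential_abundance(
    cohort: Cohort,
    features=None,
    group_col: str = "group",
    case: str = "case",
    control: str = "control",
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test between the two groups.

    log2FC is the difference of group means on the (already log2) abundance
    scale; p-values are BH-adjusted across the tested features.  Missing
    values are dropped per feature.
    """
    groups = cohort.samples[group_col]
    case_mask = (groups == case).to_numpy()
    ctrl_mask = (groups == control).to_numpy()
    if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    feats = list(features) if features is not None else list(cohort.values.columns)
    rows = []
    for f in feats:
        col = cohort.values[f].to_numpy(dtype=float)
        x = col[case_mask]
        y = col[ctrl_mask]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"feature {f!r} has an empty group after NaN removal")
        rows.append((f, float(x.mean() - y.mean()), _ranksum_p(x, y)))
    out = pd.DataFrame(rows, columns=["feature", "log2fc", "p"])
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
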