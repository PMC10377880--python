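"""Group-level statistics: rank tests, ROC AUC, correlations and PCA.

Conventions (documented because the originating software is unknown):

* all tests are two-sided;
* the Mann-Whitney U statistic is reported in the orientation that makes it
  at least ``n1 * n2 / 2``, together with a flag saying which sample ranks
  higher;
* the chi-squared test applies no continuity correction by default;
* Spearman p-values are Bonferroni-adjusted by the number of score pairs
  actually tested in the run;
* PCA operates on z-scored variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "roc_auc",
    "spearman_bonferroni",
    "pca_first_component",
    "per_second_comparison",
    "demographics_tests",
    "validate_cohort_table",
]

#: Clinical score columns recognized in cohort tables.
SCORE_COLUMNS = ("updrs3", "hoehn_yahr", "moca", "mmp")


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample Mann-Whitney result, max-oriented U plus direction."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    direction: str  # "first" | "second" | "tie": which sample ranks higher

    @property
    def u_max(self) -> float:
        return float(self.n1 * self.n2)

    def as_dict(self) -> Dict[str, float]:
        return {
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "direction": self.direction,
        }


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when ``n1 * n2 <= 400`` and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_y = x.size * y.size - u_x
    if u_x > u_y:
        direction = "first"
    elif u_y > u_x:
        direction = "second"
    else:
        direction = "tie"
    return GroupComparison(
        u_statistic=max(u_x, u_y),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        direction=direction,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str], positive: str = "groupA") -> float:
    """Area under the ROC curve with the positive class scoring higher.

    Rank-based (trapezoidal) AUC; ties receive 0.5 credit, so the identity
    ``AUC = U / (n1 * n2)`` with U oriented toward the positive class holds
    exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    # midrank formulation: U_pos / (n_pos * n_neg)
    ranks = stats.rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    u_pos = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u_pos / (n_pos * n_neg))


def spearman_bonferroni(
    table: pd.DataFrame,
    score_names: Sequence[str] = SCORE_COLUMNS,
    target: str = "mean_fd",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rank correlation of ``target`` against each score.

    Pairwise-complete rows are used per score; raw p-values are multiplied by
    the number of score pairs tested (Bonferroni), capped at 1.  A score with
    fewer than 4 complete rows or zero rank variance is reported with an NaN
    correlation and a reason.
    """
    rows = []
    testable = []
    for name in score_names:
        if name not in table.columns:
            rows.append((name, 0, np.nan, np.nan, "column missing"))
            continue
        sub = table[[target, name]].dropna()
        if len(sub) < 4:
            rows.append((name, len(sub), np.nan, np.nan, "fewer than 4 complete rows"))
            continue
        if sub[name].nunique() < 2 or sub[target].nunique() < 2:
            rows.append((name, len(sub), np.nan, np.nan, "constant column"))
            continue
        rho, p = stats.spearmanr(sub[target], sub[name])
        rows.append((name, len(sub), float(rho), float(p), ""))
        testable.append(name)

    m = max(len(testable), 1)
    out = pd.DataFrame(rows, columns=["score", "n", "rho", "p_raw", "reason"])
    out["n_comparisons"] = m
    out["p_adjusted"] = np.minimum(out["p_raw"] * m, 1.0)
    out["significant"] = out["p_adjusted"] < alpha
    return out


def pca_first_component(
    table: pd.DataFrame,
    score_names: Sequence[str] = SCORE_COLUMNS,
) -> Tuple[float, pd.Series]:
    """First principal component of the z-scored clinical scores.

    Returns the fraction of variance explained by PC1 and the per-subject PC1
    scores (complete cases only), for downstream correlation analysis.
    """
    if len(score_names) < 2:
        raise ValueError("need at least two score columns")
    data = table[list(score_names)].dropna()
    if len(data) < 3:
        raise ValueError("need at least three complete subjects")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant score column cannot be standardized")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=len(score_names))
    comp = pca.fit_transform(z)
    fraction = float(pca.explained_variance_ratio_[0])
    return fraction, pd.Series(comp[:, 0], index=data.index, name="pc1")


def per_second_comparison(series_by_group: Mapping[str, np.ndarray]) -> GroupComparison:
    """Compare the per-second group-mean FD curves of two groups.

    ``series_by_group`` maps each of exactly two group labels to an
    (n_subjects, T) array of per-window FD values.  Within each group the
    subject values are averaged per window, and the two length-T mean curves
    are compared with a Mann-Whitney U test (U reaches its ceiling T^2 under
    complete separation).
    """
    if len(series_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, a1), (g2, a2) = sorted(series_by_group.items())
    a1 = np.atleast_2d(np.asarray(a1, dtype=float))
    a2 = np.atleast_2d(np.asarray(a2, dtype=float))
    if a1.shape[1] != a2.shape[1]:
        raise ValueError(
            f"window count mismatch: {g1} has {a1.shape[1]}, {g2} has {a2.shape[1]}"
        )
    return mann_whitney(a1.mean(axis=0), a2.mean(axis=0))


def demographics_tests(table: pd.DataFrame, group_col: str = "group") -> Dict[str, dict]:
    """Between-group demographics: chi-squared for sex, U tests otherwise.

    The sex comparison uses a 2x2 chi-squared test without continuity
    correction (set ``correction`` in the returned metadata); age and
    education use Mann-Whitney U.  A contingency table with an all-zero
    margin raises.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]

    results: Dict[str, dict] = {}
    if "sex" in table.columns:
        contingency = pd.crosstab(table[group_col], table["sex"]).to_numpy()
        # crosstab omits empty categories, so a missing row/column IS a
        # zero margin of the intended 2x2 table
        if (
            contingency.shape[0] < 2
            or contingency.shape[1] < 2
            or (contingency.sum(axis=0) == 0).any()
            or (contingency.sum(axis=1) == 0).any()
        ):
            raise ValueError("contingency table has an all-zero margin")
        chi2, p, dof, _ = stats.chi2_contingency(contingency, correction=False)
        results["sex"] = {"chi2": float(chi2), "p_value": float(p), "dof": int(dof)}
    for col in ("age", "education"):
        if col in table.columns:
            cmp = mann_whitney(g1[col].dropna(), g2[col].dropna())
            results[col] = cmp.as_dict()
    return results


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort summary table (one row per subject)."""
    required = {"subject_id", "group", "mean_fd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id rows")
    if not np.isfinite(table["mean_fd"].to_numpy(dtype=float)).all():
        raise ValueError("mean_fd must be finite")
    return table
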