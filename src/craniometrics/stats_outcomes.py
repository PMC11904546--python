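"""Group comparison and quality-of-life scoring for cohort follow-up.

Covers the study-style outcome machinery:

* ``group_compare`` — comparison of a named measurement between two groups,
  by default age-adjusted: an ordinary-least-squares fit of
  ``value ~ intercept + group + age`` (classic ANCOVA without interaction),
  reporting the group coefficient with its two-sided t-distribution p
  value; without adjustment, a two-tailed two-sample t test (pooled by
  default, Welch selectable);
* ``significance_tier`` — the four-level significance labelling
  (p < 0.01 highly significant, < 0.05 significant, < 0.1 mildly
  significant, otherwise not significant; half-open intervals, boundaries
  belong to the weaker tier);
* ``kidscreen_scores`` — KIDSCREEN-52 category sum scores linearly rescaled
  to 0–100 (all-1 responses map to 0, all-5 to 100; higher = better HRQOL);
  a one-based 1–100 variant is selectable;
* ``percentile_band`` — locating a category score among user-supplied norm
  percentiles (P10/P25/P50/P75/P90), boundaries inclusive on the lower
  edge.

Official Rasch-based KIDSCREEN T-scoring is intentionally out of scope; the
package scores plain category sums and leaves norm values to the user (a
small illustrative synthetic norm table ships for demonstrations only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CollinearDesignError, ValidationError

SIGNIFICANCE_TIERS = (
    "highly significant",
    "significant",
    "mildly significant",
    "not significant",
)


def significance_tier(p: float) -> str:
    """Map a p value to its significance label (monotone step function)."""
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        raise ValidationError(f"p value {p!r} outside [0, 1]")
    if p < 0.01:
        return "highly significant"
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "mildly significant"
    return "not significant"


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group comparison on one measurement."""

    value_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    difference: float  # group_b minus group_a (age-adjusted when requested)
    p_value: float
    method: str

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "value_name", "group_a", "group_b", "n_a", "n_b",
            "mean_a", "mean_b", "difference", "p_value", "method",
        )}
        d["tier"] = self.tier
        return d


def validate_cohort(cohort: pd.DataFrame, require_age: bool = False) -> None:
    """Check the cohort table contract: subject/group columns, positive ages,
    no duplicated (subject, timepoint) rows."""
    for col in ("subject", "group"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table lacks required column {col!r}")
    if require_age:
        if "age_months" not in cohort.columns:
            raise ValidationError("cohort table lacks 'age_months' needed for age adjustment")
        if (cohort["age_months"] <= 0).any():
            raise ValidationError("ages must be positive")
    if "timepoint" in cohort.columns:
        if cohort.duplicated(["subject", "timepoint"]).any():
            raise ValidationError("duplicate (subject, timepoint) rows in cohort table")


def _ols_group_age(y: np.ndarray, g: np.ndarray, age: np.ndarray) -> tuple[float, float]:
    """OLS fit of y on [1, group, age]; returns (group coefficient, p value).

    The design is solved through the normal equations; the p value is the
    two-sided tail of the t distribution with n - 3 degrees of freedom.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), g, age])
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < 3 or np.linalg.cond(XtX) > 1e12:
        raise CollinearDesignError(
            "collinear design: age is confounded with group (or constant)"
        )
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - 3
    if dof <= 0:
        raise ValidationError("too few subjects for the age-adjusted model")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(cov[1, 1])
    tstat = beta[1] / se if se > 0 else np.inf
    p = 2.0 * sps.t.sf(abs(tstat), dof)
    return float(beta[1]), float(min(p, 1.0))


def group_compare(
    cohort: pd.DataFrame,
    value_name: str,
    group_a: str,
    group_b: str,
    adjust_age: bool = True,
    welch: bool = False,
) -> GroupComparison:
    """Compare ``value_name`` between two group labels of a cohort table.

    With ``adjust_age`` (default), the adjusted difference is the group
    coefficient of the linear model ``value = b0 + b1*group + b2*age``
    (group coded 0 for ``group_a``, 1 for ``group_b``); otherwise a
    two-tailed two-sample t test is run (pooled variance, or Welch when
    ``welch=True``).  Observed (unadjusted) group means are always
    reported.
    """
    validate_cohort(cohort, require_age=adjust_age)
    if value_name not in cohort.columns:
        raise ValidationError(f"cohort table lacks measurement column {value_name!r}")
    sub = cohort[cohort["group"].isin([group_a, group_b])].dropna(subset=[value_name])
    ya = sub.loc[sub["group"] == group_a, value_name].to_numpy(dtype=float)
    yb = sub.loc[sub["group"] == group_b, value_name].to_numpy(dtype=float)
    if len(ya) < 3 or len(yb) < 3:
        raise ValidationError("need at least 3 subjects per group")

    if adjust_age:
        part = sub[sub["group"].isin([group_a, group_b])]
        y = part[value_name].to_numpy(dtype=float)
        g = (part["group"] == group_b).to_numpy(dtype=float)
        age = part["age_months"].to_numpy(dtype=float)
        diff, p = _ols_group_age(y, g, age)
        method = "ancova_age"
    else:
        diff = float(yb.mean() - ya.mean())
        res = sps.ttest_ind(yb, ya, equal_var=not welch)
        p = float(res.pvalue)
        method = "welch_t" if welch else "pooled_t"

    return GroupComparison(
        value_name=value_name,
        group_a=group_a,
        group_b=group_b,
        n_a=len(ya),
        n_b=len(yb),
        mean_a=float(ya.mean()),
        mean_b=float(yb.mean()),
        difference=diff,
        p_value=p,
        method=method,
    )


# ---------------------------------------------------------------------------
# KIDSCREEN-52 scoring

#: default item -> category map: 52 items ("q1".."q52") over 10 categories,
#: following the instrument's published category sizes.
DEFAULT_ITEM_MAP: dict[str, str] = {}
_CATEGORY_SIZES = [
    ("physical_wellbeing", 5),
    ("psychological_wellbeing", 6),
    ("moods_emotions", 7),
    ("self_perception", 5),
    ("autonomy", 5),
    ("parent_relations_home", 6),
    ("financial_resources", 3),
    ("social_support_peers", 6),
    ("school_environment", 6),
    ("social_acceptance", 3),
]
_i = 1
for _cat, _size in _CATEGORY_SIZES:
    for _ in range(_size):
        DEFAULT_ITEM_MAP[f"q{_i}"] = _cat
        _i += 1
del _i, _cat, _size


def kidscreen_scores(
    responses: pd.DataFrame,
    item_map: dict[str, str] | None = None,
    min_complete: float = 1.0,
    one_based: bool = False,
) -> pd.DataFrame:
    """Per-subject, per-category sum scores rescaled to 0–100.

    ``responses`` is indexed by subject with one column per item, responses
    in 1..5 (NaN = missing).  For a category of ``n`` items with raw sum
    ``s``, the score is ``100 * (s - n) / (4 n)``: all-1 responses map to 0
    and all-5 to 100, higher meaning better health-related quality of life.
    With ``one_based=True`` the variant ``1 + 99 * (s - n) / (4 n)`` on a
    1–100 scale is returned instead.

    A subject-category with a completed-item fraction below ``min_complete``
    (default: all items required) is reported as NaN, never imputed.
    """
    item_map = DEFAULT_ITEM_MAP if item_map is None else item_map
    missing_items = [i for i in item_map if i not in responses.columns]
    if missing_items:
        raise ValidationError(f"response table lacks item columns: {missing_items[:5]} ...")
    vals = responses[list(item_map)]
    bad = vals.stack(future_stack=True).dropna()
    if ((bad < 1) | (bad > 5)).any():
        raise ValidationError("item responses must lie in 1..5")

    categories = sorted(set(item_map.values()))
    out = {}
    for cat in categories:
        items = [i for i, c in item_map.items() if c == cat]
        block = vals[items]
        n_items = len(items)
        complete = block.notna().sum(axis=1) / n_items
        raw = block.sum(axis=1, min_count=n_items)
        score = 100.0 * (raw - n_items) / (4.0 * n_items)
        if one_based:
            score = 1.0 + 99.0 * (raw - n_items) / (4.0 * n_items)
        score[complete < min_complete] = np.nan
        out[cat] = score
    return pd.DataFrame(out, index=responses.index)


PERCENTILES = (10, 25, 50, 75, 90)
BAND_LABELS = ("<P10", "P10-P25", "P25-P50", "P50-P75", "P75-P90", ">P90")


def load_norms(path=None) -> pd.DataFrame:
    """Read a norm table (CSV: category, mean, sd, p10, p25, p50, p75, p90).

    Without a path, the shipped *synthetic illustrative* norm file is
    loaded; it is NOT official reference data and exists only so the band
    lookup can be demonstrated end to end.
    """
    if path is None:
        path = resources.files("craniometrics").joinpath("data", "synthetic_norms.csv")
        with path.open("r") as fh:
            norms = pd.read_csv(fh)
    else:
        norms = pd.read_csv(path)
    required = {"category", "p10", "p25", "p50", "p75", "p90"}
    if not required.issubset(norms.columns):
        raise ValidationError(f"norm table must contain columns {sorted(required)}")
    return norms.set_index("category")


def percentile_band(score: float, norms: pd.DataFrame, category: str) -> str:
    """Band containing ``score`` among a category's norm percentile cuts.

    Boundaries are inclusive on the lower edge: a score exactly at the P50
    cut is reported as P50-P75.
    """
    if category not in norms.index:
        raise ValidationError(f"category {category!r} missing from norm table")
    cuts = norms.loc[category, ["p10", "p25", "p50", "p75", "p90"]].to_numpy(dtype=float)
    if np.any(np.diff(cuts) < 0):
        raise ValidationError(f"norm percentiles for {category!r} are not non-decreasing")
    if not np.isfinite(score):
        raise ValidationError("score is not finite")
    idx = int(np.searchsorted(cuts, score, side="right"))
    return BAND_LABELS[idx]
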