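"""Filter-stage feature selection: per-patient ANOVA and rank-sum tests.

For every feature and every patient possessing both apnea and normal
minutes, a pair of two-sided tests compares the apnea-minute values against
the normal-minute values: a one-way two-group ANOVA and a Wilcoxon rank-sum
test (mid-ranks for ties; exact null for small samples without ties, normal
approximation with tie correction otherwise).  The pair is *positive* when
the ANOVA p-value is below alpha and the rank-sum test rejects at alpha.

``lambda`` for a feature is the number of patients with a positive pair;
``nu`` is the number of contributing patients.  Features with lambda >= 1
are selected, and the selected features are stratified into classes
A (lambda = nu) through E (lambda = nu - 4).

No multiple-testing correction is applied: the counts are used as a
ranking, not as inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import registry

log = logging.getLogger(__name__)

ALPHA = 0.05
CLASS_ORDER = ("A", "B", "C", "D", "E")


def anova_p(group_a: np.ndarray, group_n: np.ndarray
            ) -> tuple[float, float, int, int]:
    """One-way two-group ANOVA: returns (F, p, df_group, df_error)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_n, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(a), len(b)
    grand = (a.sum() + b.sum()) / (n1 + n2)
    ssg = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_group, df_error = 1, n1 + n2 - 2
    if sse == 0.0:
        if ssg == 0.0:
            return 0.0, 1.0, df_group, df_error
        log.debug("zero within-group variance with unequal means; p = 0")
        return float("inf"), 0.0, df_group, df_error
    f_ratio = (ssg / df_group) / (sse / df_error)
    p = float(stats.f.sf(f_ratio, df_group, df_error))
    return float(f_ratio), p, df_group, df_error


def ranksum_decision(group_a: np.ndarray, group_n: np.ndarray,
                     alpha: float = ALPHA) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum p-value and rejection flag.

    Exact null distribution when min(n1, n2) <= 10 and there are no ties,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_n, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return p, p < alpha


@dataclass
class SelectionResult:
    """Outcome of the filter stage."""

    lambda_: dict[str, int]
    nu_psg: int
    selected: list[str]
    class_of: dict[str, str] = field(default_factory=dict)
    tests: pd.DataFrame | None = None  # per (feature, patient) test detail

    def class_members(self, label: str) -> list[str]:
        return [c for c, lab in self.class_of.items() if lab == label]


def lambda_counts(features: pd.DataFrame, alpha: float = ALPHA) -> SelectionResult:
    """Count positive (ANOVA, rank-sum) pairs per feature across patients.

    ``features``: table from :mod:`apneapsg.pipeline` with ``record_id``,
    ``label`` and the 87 feature columns.  Only patients with both apnea and
    normal minutes contribute; all-normal (or all-apnea) records are skipped
    with a log message.
    """
    feature_cols = [c for c in registry.FEATURE_COLUMNS if c in features.columns]
    contributing: list[str] = []
    rows: list[dict] = []
    lam = {c: 0 for c in feature_cols}
    for rid, table in features.groupby("record_id", sort=True):
        labels = set(table["label"])
        if labels != {"A", "N"}:
            log.info("record %s has labels %s only; skipped in selection",
                     rid, sorted(labels))
            continue
        contributing.append(str(rid))
        grp_a = table[table["label"] == "A"]
        grp_n = table[table["label"] == "N"]
        for col in feature_cols:
            va = grp_a[col].dropna().to_numpy(float)
            vn = grp_n[col].dropna().to_numpy(float)
            if len(va) < 2 or len(vn) < 2:
                log.debug("feature %s missing for record %s; pair skipped", col, rid)
                continue
            f_ratio, p_a, dfg, dfe = anova_p(va, vn)
            p_r, reject = ranksum_decision(va, vn, alpha)
            positive = (p_a < alpha) and reject
            lam[col] += int(positive)
            rows.append({
                "feature": col, "patient_id": rid, "F": f_ratio,
                "p_anova": p_a, "df_group": dfg, "df_error": dfe,
                "p_ranksum": p_r, "ranksum_reject": reject,
                "positive_pair": positive,
            })
    nu = len(contributing)
    selected = [c for c in feature_cols if lam[c] >= 1]
    result = SelectionResult(lambda_=lam, nu_psg=nu, selected=selected,
                             tests=pd.DataFrame(rows))
    return assign_classes(result)


def assign_classes(sr: SelectionResult) -> SelectionResult:
    """Stratify selected features into classes A (lambda = nu) .. E (nu-4)."""
    class_of: dict[str, str] = {}
    for col, lam in sr.lambda_.items():
        offset = sr.nu_psg - lam
        if lam >= 1 and 0 <= offset < len(CLASS_ORDER):
            class_of[col] = CLASS_ORDER[offset]
        else:
            class_of[col] = "NONE"
    sr.class_of = class_of
    return sr


def select_from_printed_lambda(lambdas: pd.Series | None = None, nu: int = 5
                               ) -> SelectionResult:
    """Apply the lambda >= 1 rule and class partition to a published
    per-feature lambda column (defaults to the packaged fixture, indexed by
    feature number)."""
    if lambdas is None:
        lambdas = registry.published_lambda()
    lam = {registry.by_number(int(num)).column: int(v) for num, v in lambdas.items()}
    selected = [c for c, v in lam.items() if v >= 1]
    return assign_classes(SelectionResult(lambda_=lam, nu_psg=nu, selected=selected))


def selection_report(sr: SelectionResult) -> pd.DataFrame:
    """One row per feature: lambda, class, and selection flag."""
    rows = []
    for f in registry.FEATURES:
        col = f.column
        if col not in sr.lambda_:
            continue
        rows.append({
            "number": f.number, "feature": col, "lambda": sr.lambda_[col],
            "class": sr.class_of.get(col, "NONE"),
            "selected": col in sr.selected,
        })
    return pd.DataFrame(rows)
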