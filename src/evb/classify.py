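"""Two-marker molecular-pathology classification and diagnostic performance.

The two tau-ratio cut-offs and two TDP-43 cut-offs partition the
(3R/4R tau ratio, EV TDP-43) plane into a 3x3 grid that maps each subject
to a putative molecular pathology: a low tau ratio flags PSP/GGT-type 4R
tauopathy, a high ratio flags FTLD-tau of the MAPT kind, an intermediate
ratio with at least mildly elevated TDP-43 flags TDP-43 pathology (with a
"high" severity sub-flag above the upper TDP-43 cut-off), and everything
else is control-like.  Sensitivity and specificity against confirmed
pathology carry exact (Clopper-Pearson) binomial confidence intervals, and
one cohort's rule can be transferred to another cohort's subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassificationRule",
    "DiagnosticPerformance",
    "clopper_pearson",
    "classify_subject",
    "classify_table",
    "diagnostic_performance",
    "transfer_cutoffs",
    "LABEL_PSP_LIKE",
    "LABEL_TAU_LIKE",
    "LABEL_TDP",
    "LABEL_CONTROL",
    "LABEL_UNCLASSIFIABLE",
]

LABEL_PSP_LIKE = "PSP/GGT-type tauopathy-like"
LABEL_TAU_LIKE = "FTLD-tau (MAPT-like)"
LABEL_TDP = "TDP-43-positive"
LABEL_CONTROL = "control-like"
LABEL_UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ClassificationRule:
    """The four cut-offs of the two-marker decision grid, with provenance.

    ``tau_lower``/``tau_upper`` bound the intermediate tau-ratio band;
    ``tdp_lower`` is the "at least mildly increased" TDP-43 threshold that
    all performance claims use; ``tdp_upper`` is the informational severity
    threshold.  ``provenance`` records where the numbers came from (fitted
    model, cohort, published value, ...).
    """

    tau_lower: float
    tau_upper: float
    tdp_lower: float
    tdp_upper: float
    cohort: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tau_lower < self.tau_upper:
            raise ValueError("tau cut-offs must satisfy lower < upper")
        if not self.tdp_lower < self.tdp_upper:
            raise ValueError("TDP-43 cut-offs must satisfy lower < upper")


#: The published discovery-cohort rule (text value 1.27 for the upper tau
#: cut-off; the figure legend prints 1.28 — recorded in provenance).
DESCRIBE_RULE = ClassificationRule(
    tau_lower=0.77,
    tau_upper=1.27,
    tdp_lower=13.87,
    tdp_upper=56.18,
    cohort="DESCRIBE-2",
    provenance={"source": "published", "tau_upper_note": "1.27 in text, 1.28 in the grid figure legend"},
)

#: The published validation-cohort rule.
SANT_PAU_RULE = ClassificationRule(
    tau_lower=0.78,
    tau_upper=1.28,
    tdp_lower=17.85,
    tdp_upper=57.34,
    cohort="SantPau",
    provenance={"source": "published"},
)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts with sensitivity/specificity and exact binomial CIs.

    Percentages; an estimate whose truth denominator is empty is NaN with
    ``undefined`` flagged in the corresponding attribute.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    conf_level: float = 0.95
    sens_undefined: bool = False
    spec_undefined: bool = False


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, in percent.

    ``lo = BetaInv(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``hi = BetaInv(1-alpha/2; x+1, n-x)`` (1 when x = n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    alpha = 1.0 - conf_level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return 100.0 * lo, 100.0 * hi


def classify_subject(tau_ratio: float, tdp43: float, rule: ClassificationRule) -> tuple[str, dict]:
    """Assign the putative molecular-pathology label for one subject.

    Returns ``(label, flags)``; ``flags`` may contain ``high_tdp`` (TDP-43
    above the severity cut-off) and ``conflict`` (a tau label coinciding
    with elevated TDP-43 — reported, not resolved).  Missing markers give
    the "unclassifiable" label.
    """
    if tau_ratio is None or tdp43 is None or not (np.isfinite(tau_ratio) and np.isfinite(tdp43)):
        return LABEL_UNCLASSIFIABLE, {}
    flags: dict = {}
    elevated_tdp = tdp43 > rule.tdp_lower
    if tdp43 > rule.tdp_upper:
        flags["high_tdp"] = True
    if tau_ratio < rule.tau_lower:
        if elevated_tdp:
            flags["conflict"] = True
        return LABEL_PSP_LIKE, flags
    if tau_ratio > rule.tau_upper:
        if elevated_tdp:
            flags["conflict"] = True
        return LABEL_TAU_LIKE, flags
    if elevated_tdp:
        return LABEL_TDP, flags
    return LABEL_CONTROL, flags


def classify_table(table: pd.DataFrame, rule: ClassificationRule) -> pd.DataFrame:
    """Vectorised grid classification of a cohort table.

    Adds ``predicted`` plus boolean ``flag_high_tdp`` / ``flag_conflict``
    columns; the input is not modified.
    """
    out = table.copy()
    labels = []
    high = []
    conflict = []
    for tau, tdp in zip(out["tau_ratio"].to_numpy(), out["tdp43"].to_numpy()):
        label, flags = classify_subject(tau, tdp, rule)
        labels.append(label)
        high.append(bool(flags.get("high_tdp", False)))
        conflict.append(bool(flags.get("conflict", False)))
    out["predicted"] = labels
    out["flag_high_tdp"] = high
    out["flag_conflict"] = conflict
    return out


def diagnostic_performance(predictions, truth, conf_level: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity and specificity (percent) with exact binomial CIs.

    ``predictions`` and ``truth`` are equal-length boolean vectors.  A truth
    vector with no positives (or no negatives) leaves the corresponding
    estimate NaN-flagged rather than raising.
    """
    pred = np.asarray(predictions, dtype=bool).ravel()
    true = np.asarray(truth, dtype=bool).ravel()
    if pred.size != true.size:
        raise ValueError("predictions and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty vectors")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))

    def rate_ci(x: int, n: int) -> tuple[float, tuple[float, float], bool]:
        if n == 0:
            return float("nan"), (float("nan"), float("nan")), True
        return 100.0 * x / n, clopper_pearson(x, n, conf_level), False

    sens, sens_ci, sens_undef = rate_ci(tp, tp + fn)
    spec, spec_ci, spec_undef = rate_ci(tn, tn + fp)
    return DiagnosticPerformance(tp, fp, tn, fn, sens, sens_ci, spec, spec_ci, conf_level, sens_undef, spec_undef)


def _truth_vector(table: pd.DataFrame, truth_spec: dict) -> tuple[np.ndarray, pd.DataFrame]:
    """Resolve a truth specification against a cohort table.

    ``truth_spec`` keys: ``positive`` (pathology labels or diagnoses counted
    as positive truth), ``column`` ("pathology" by default or "diagnosis"),
    and optional ``restrict_to`` (labels defining the evaluation denominator;
    default: confirmed cases only, i.e. pathology != unknown, when the truth
    column is pathology, else all rows).
    """
    column = truth_spec.get("column", "pathology")
    if column not in table.columns:
        raise ValueError(f"truth column {column!r} absent from table")
    positive = set(truth_spec["positive"])
    col = table[column]
    if "restrict_to" in truth_spec:
        sub = table[col.isin(set(truth_spec["restrict_to"]))]
    elif column == "pathology":
        sub = table[col != "unknown"]
    else:
        sub = table
    return sub[column].isin(positive).to_numpy(), sub


def transfer_cutoffs(
    rule_from_cohort_a: ClassificationRule,
    table_b: pd.DataFrame,
    truth_spec: dict,
    predicted_positive=(LABEL_TDP,),
    native_rule: ClassificationRule | None = None,
    conf_level: float = 0.95,
) -> dict:
    """Score cohort A's classification rule on cohort B's truth.

    Classifies cohort B with the foreign rule, compares predictions against
    the truth defined by ``truth_spec``, and, when ``native_rule`` is
    supplied, reports the native performance side-by-side.
    ``predicted_positive`` is either a collection of grid labels or the
    string ``"tdp_elevated"``, the simple one-marker test "TDP-43 above the
    lower cut-off" that the published detection claims use.  Returns
    ``{"transferred": DiagnosticPerformance, "native": ...}``.
    """
    truth, sub = _truth_vector(table_b, truth_spec)
    if truth.size == 0:
        raise ValueError("truth specification selects no rows")

    def score(rule: ClassificationRule) -> DiagnosticPerformance:
        if predicted_positive == "tdp_elevated":
            pred = (sub["tdp43"] > rule.tdp_lower).to_numpy()
        else:
            classified = classify_table(sub, rule)
            pred = classified["predicted"].isin(set(predicted_positive)).to_numpy()
        return diagnostic_performance(pred, truth, conf_level)

    return {
        "transferred": score(rule_from_cohort_a),
        "native": score(native_rule) if native_rule is not None else None,
    }
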