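"""Diagnostic-accuracy statistics for a screener against a reference standard.

Implements the 2x2 confusion table, sensitivity / specificity / predictive
values / accuracy with exact (Clopper-Pearson) binomial confidence intervals,
likelihood ratios and post-test odds, the ROC over the screener's integer
cutpoints with empirical (trapezoidal) AUC, optimal-cutpoint rules, and
per-demographic-subgroup accuracy summaries.

Two distinct "ROC area" quantities are exposed because both appear in
published accuracy tables: ``roc_area_single`` = (sensitivity+specificity)/2
for a single operating point, and ``auc_empirical``, the trapezoidal area
through all cutpoint operating points anchored at (0,0) and (1,1).

Any metric whose denominator is zero is reported as an explicit undefined
marker (value ``None`` with a reason), never silently as 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .instruments import REFERENCE_CUTPOINT, derive_marsha_c_from_marsha  # noqa: F401
from .schema import SCREENER_ITEMS

__all__ = [
    "ConfusionTable",
    "ExactCI",
    "Estimate",
    "DiagnosticMetrics",
    "LikelihoodRatios",
    "RocPoint",
    "RocAnalysis",
    "confusion_table",
    "exact_binomial_ci",
    "metrics",
    "likelihood_ratios",
    "roc_curve",
    "select_cutpoint",
    "subgroup_analysis",
    "reconstruct_confusion_table",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of reference class vs screener class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        """Reference-positive count."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Reference-negative count."""
        return self.fp + self.tn

    @property
    def screen_positives(self) -> int:
        return self.tp + self.fp

    @property
    def prevalence(self) -> float:
        """Reference prevalence (tp+fn)/n."""
        if self.n == 0:
            raise ValueError("empty table has no prevalence")
        return self.positives / self.n

    @property
    def screen_positive_rate(self) -> float:
        if self.n == 0:
            raise ValueError("empty table has no screen-positive rate")
        return self.screen_positives / self.n


def confusion_table(reference: Sequence, screen: Sequence) -> ConfusionTable:
    """Cross-tabulate paired binary reference and screener classifications."""
    ref = np.asarray([bool(r) for r in reference], dtype=bool)
    scr = np.asarray([bool(s) for s in screen], dtype=bool)
    if ref.shape != scr.shape:
        raise ValueError(f"length mismatch: {len(ref)} reference vs {len(scr)} screen")
    return ConfusionTable(
        tp=int(np.sum(ref & scr)),
        fn=int(np.sum(ref & ~scr)),
        fp=int(np.sum(~ref & scr)),
        tn=int(np.sum(~ref & ~scr)),
    )


@dataclass(frozen=True)
class ExactCI:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper <= 1:
            raise ValueError("require 0 <= lower <= upper <= 1")


def exact_binomial_ci(successes: int, trials: int, level: float = 0.95) -> ExactCI:
    """Clopper-Pearson exact confidence interval for a binomial proportion.

    The exact interval inverts binomial tail probabilities (equivalently, beta
    quantiles); it is conservative (coverage at least nominal) and handles the
    degenerate endpoints: lower = 0 when ``successes`` = 0 and upper = 1 when
    ``successes`` = ``trials``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lower, upper = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    return ExactCI(lower=float(lower), upper=float(upper), level=level)


@dataclass(frozen=True)
class Estimate:
    """A proportion with its exact CI, or an explicit undefined marker."""

    value: float | None
    ci: ExactCI | None = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.value is not None


_UNDEFINED = Estimate(value=None, ci=None, note="NA (zero denominator)")


def _proportion_estimate(successes: int, trials: int, level: float) -> Estimate:
    if trials == 0:
        return _UNDEFINED
    return Estimate(value=successes / trials, ci=exact_binomial_ci(successes, trials, level))


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    table: ConfusionTable
    level: float = 0.95

    @property
    def roc_area_single(self) -> float | None:
        """Single-cutpoint ROC area (sensitivity + specificity) / 2."""
        if self.sensitivity.defined and self.specificity.defined:
            return (self.sensitivity.value + self.specificity.value) / 2
        return None


def metrics(table: ConfusionTable, level: float = 0.95) -> DiagnosticMetrics:
    """All accuracy metrics with exact CIs, each on its own denominator."""
    if table.n == 0:
        raise ValueError("cannot compute metrics on an empty table")
    return DiagnosticMetrics(
        sensitivity=_proportion_estimate(table.tp, table.positives, level),
        specificity=_proportion_estimate(table.tn, table.negatives, level),
        ppv=_proportion_estimate(table.tp, table.screen_positives, level),
        npv=_proportion_estimate(table.tn, table.tn + table.fn, level),
        accuracy=_proportion_estimate(table.tp + table.tn, table.n, level),
        table=table,
        level=level,
    )


@dataclass(frozen=True)
class LikelihoodRatios:
    """Likelihood ratios and post-test odds at a given pre-test prevalence.

    ``lr_positive`` is ``inf`` at perfect specificity; post-test odds multiply
    the pre-test odds by the corresponding likelihood ratio.
    """

    lr_positive: float
    lr_negative: float
    pretest_prevalence: float
    post_test_odds_positive: float = field(init=False)
    post_test_odds_negative: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.pretest_prevalence < 1:
            raise ValueError("pretest prevalence must be in (0, 1)")
        odds = self.pretest_prevalence / (1 - self.pretest_prevalence)
        object.__setattr__(self, "post_test_odds_positive", odds * self.lr_positive)
        object.__setattr__(self, "post_test_odds_negative", odds * self.lr_negative)


def likelihood_ratios(
    table: ConfusionTable, pretest_prevalence: float | None = None
) -> LikelihoodRatios:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, with post-test odds.

    The pre-test prevalence defaults to the sample reference prevalence and
    may be overridden for an external target population.
    """
    m = metrics(table)
    if not (m.sensitivity.defined and m.specificity.defined):
        raise ValueError("likelihood ratios need both classes present")
    sens, spec = m.sensitivity.value, m.specificity.value
    lr_pos = math.inf if spec == 1.0 else sens / (1 - spec)
    lr_neg = math.nan if spec == 0.0 else (1 - sens) / spec
    if pretest_prevalence is None:
        pretest_prevalence = table.prevalence
    return LikelihoodRatios(
        lr_positive=lr_pos, lr_negative=lr_neg, pretest_prevalence=pretest_prevalence
    )


@dataclass(frozen=True)
class RocPoint:
    cutpoint: int
    sensitivity: float
    false_positive_rate: float

    @property
    def specificity(self) -> float:
        return 1 - self.false_positive_rate

    @property
    def youden(self) -> float:
        return self.sensitivity - self.false_positive_rate

    @property
    def distance_to_corner(self) -> float:
        """Euclidean distance to the ideal corner (FPR 0, sensitivity 1)."""
        return math.hypot(self.false_positive_rate, 1 - self.sensitivity)


CutpointRule = Literal["closest_to_corner", "youden"]


@dataclass(frozen=True)
class RocAnalysis:
    points: tuple[RocPoint, ...]
    auc_empirical: float
    selected_cutpoint: int
    selection_rule: CutpointRule


def _trapezoid_auc(points: Sequence[RocPoint]) -> float:
    coords = sorted(
        [(0.0, 0.0), (1.0, 1.0)] + [(p.false_positive_rate, p.sensitivity) for p in points]
    )
    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    return float(np.trapezoid(ys, xs))


def select_cutpoint(
    points: Sequence[RocPoint] | RocAnalysis, rule: CutpointRule = "closest_to_corner"
) -> int:
    """Choose the operating cutpoint from ROC points.

    ``closest_to_corner`` minimizes the Euclidean distance to the top-left
    corner (perfect sensitivity and specificity); ``youden`` maximizes
    J = sensitivity + specificity - 1.  Ties go to the smaller cutpoint.
    """
    if isinstance(points, RocAnalysis):
        points = points.points
    if not points:
        raise ValueError("no ROC points")
    if rule == "closest_to_corner":
        return min(points, key=lambda p: (p.distance_to_corner, p.cutpoint)).cutpoint
    if rule == "youden":
        return min(points, key=lambda p: (-p.youden, p.cutpoint)).cutpoint
    raise ValueError(f"unknown rule {rule!r}")


def roc_curve(
    scores: Sequence[int],
    reference: Sequence,
    cutpoints: Sequence[int] = (1, 2, 3),
    selection_rule: CutpointRule = "closest_to_corner",
) -> RocAnalysis:
    """ROC over the screener's integer cutpoints.

    Each cutpoint contributes the operating point (sensitivity, 1-specificity)
    of the rule "score >= cutpoint".  The empirical AUC is the trapezoidal
    area through these points anchored at (0,0) and (1,1).
    """
    scr = np.asarray(scores)
    ref = np.asarray([bool(r) for r in reference])
    if scr.shape != ref.shape:
        raise ValueError("scores and reference must be paired")
    n_pos, n_neg = int(ref.sum()), int((~ref).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative reference")
    pts = []
    for c in cutpoints:
        pred = scr >= c
        pts.append(
            RocPoint(
                cutpoint=int(c),
                sensitivity=float(np.sum(pred & ref) / n_pos),
                false_positive_rate=float(np.sum(pred & ~ref) / n_neg),
            )
        )
    pts_t = tuple(pts)
    return RocAnalysis(
        points=pts_t,
        auc_empirical=_trapezoid_auc(pts_t),
        selected_cutpoint=select_cutpoint(pts_t, selection_rule),
        selection_rule=selection_rule,
    )


def subgroup_analysis(
    records: pd.DataFrame,
    grouping: str,
    cutpoint: int = 1,
    level: float = 0.95,
    min_n: int = 100,
    screener_items: Sequence[str] = SCREENER_ITEMS,
    reference_cutpoint: int = REFERENCE_CUTPOINT,
    item_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-demographic-subgroup accuracy at a fixed screener cutpoint.

    Returns one row per group plus a ``full_sample`` row, with sample size,
    reference prevalence, screen-positive rate, the five accuracy metrics,
    the single-cutpoint ROC area (sens+spec)/2, and an ``exploratory`` flag
    for groups below ``min_n``.  Groups with only one reference class get
    undefined (NaN) metrics rather than being dropped.
    """
    if grouping not in records.columns:
        raise KeyError(f"grouping column {grouping!r} not present")
    if item_ids is None:
        from .schema import DEFAULT_SCHEMA

        item_ids = [c for c in DEFAULT_SCHEMA.item_ids if c in records.columns]
    item_df = records.loc[:, list(item_ids)].apply(pd.to_numeric, errors="coerce")
    ref = item_df.fillna(0).sum(axis=1) >= reference_cutpoint
    scr_score = (item_df[list(screener_items)].fillna(0) > 0).sum(axis=1)
    scr = scr_score >= cutpoint

    def one_row(label: str, mask: np.ndarray) -> dict:
        t = confusion_table(ref[mask], scr[mask])
        row: dict = {
            "group": label,
            "n": t.n,
            "prevalence": t.prevalence if t.n else np.nan,
            "screen_positive_rate": t.screen_positive_rate if t.n else np.nan,
            "exploratory": bool(t.n < min_n) and label != "full_sample",
        }
        m = metrics(t, level)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est: Estimate = getattr(m, name)
            row[name] = est.value if est.defined else np.nan
            row[f"{name}_lo"] = est.ci.lower if est.ci else np.nan
            row[f"{name}_hi"] = est.ci.upper if est.ci else np.nan
        row["roc_area_single"] = (
            m.roc_area_single if m.roc_area_single is not None else np.nan
        )
        return row

    rows = [one_row("full_sample", np.ones(len(records), dtype=bool))]
    for gval, idx in records.groupby(grouping, sort=True).groups.items():
        rows.append(one_row(str(gval), records.index.isin(idx)))
    return pd.DataFrame(rows)


def reconstruct_confusion_table(
    n: int,
    n_reference_positive: int,
    sensitivity: float,
    specificity: float,
    ppv: float,
    npv: float,
    accuracy: float,
    require_unique: bool = True,
) -> ConfusionTable:
    """Recover the integer 2x2 table behind published rounded metrics.

    Exhaustively searches all tables with the stated total ``n`` and
    reference-positive count, returning the one minimizing the maximum
    absolute deviation across the five published metrics.  With
    ``require_unique`` the runner-up must be clearly worse, guarding against
    ambiguous reconstructions.
    """
    n_neg = n - n_reference_positive
    targets = dict(sens=sensitivity, spec=specificity, ppv=ppv, npv=npv, acc=accuracy)
    scored: list[tuple[float, int, int]] = []
    for tp in range(n_reference_positive + 1):
        fn = n_reference_positive - tp
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            if tp + fp == 0 or fn + tn == 0:
                continue
            vals = dict(
                sens=tp / n_reference_positive,
                spec=tn / n_neg,
                ppv=tp / (tp + fp),
                npv=tn / (tn + fn),
                acc=(tp + tn) / n,
            )
            dev = max(abs(vals[k] - v) for k, v in targets.items())
            scored.append((dev, tp, fp))
    scored.sort()
    best_dev, tp, fp = scored[0]
    if require_unique and len(scored) > 1 and scored[1][0] < 2 * best_dev:
        raise ValueError(
            "reconstruction ambiguous: runner-up table deviates "
            f"{scored[1][0]:.4g} vs best {best_dev:.4g}"
        )
    return ConfusionTable(tp=tp, fn=n_reference_positive - tp, fp=fp, tn=n_neg - fp)
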