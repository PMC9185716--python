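"""Publication-style rendering of accuracy results.

Produces the two standard table layouts: accuracy by screener cutpoint
(sensitivity/specificity/PPV/NPV with exact 95% CIs and the screen-positive
rate) and accuracy by demographic subgroup at a fixed cutpoint (with the
single-cutpoint ROC area).  Rounding follows the conventions of published
accuracy tables: percentages to one decimal, areas to three, half-up.
Undefined metrics render as "NA (zero denominator)".  Machine-readable JSON
carries the same numbers as the delimited-text tables.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticMetrics, Estimate, RocAnalysis

NA_CELL = "NA (zero denominator)"


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding (3 dp of 0.8715 -> 0.872 not banker's 0.871)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float | None, digits: int = 1) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return NA_CELL
    return f"{round_half_up(100 * x, digits):.{digits}f}%"


def format_estimate(est: Estimate) -> str:
    """``83.8% (75.8%-89.9%)`` or the NA marker."""
    if not est.defined:
        return NA_CELL
    cell = format_percent(est.value)
    if est.ci is not None:
        cell += f" ({format_percent(est.ci.lower)}-{format_percent(est.ci.upper)})"
    return cell


_METRIC_COLUMNS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def render_cutpoint_table(
    metrics_by_cutpoint: Mapping[int, DiagnosticMetrics]
) -> pd.DataFrame:
    """Accuracy-by-cutpoint table, one formatted row per cutpoint."""
    if not metrics_by_cutpoint:
        raise ValueError("no metrics to render")
    rows = []
    for cut, m in sorted(metrics_by_cutpoint.items()):
        rows.append(
            {
                "cutpoint": cut,
                "screen_positive_pct": format_percent(m.table.screen_positive_rate),
                **{name: format_estimate(getattr(m, name)) for name in _METRIC_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def render_subgroup_table(subgroups: pd.DataFrame) -> pd.DataFrame:
    """Accuracy-by-subgroup table from :func:`diagnostics.subgroup_analysis`."""
    rows = []
    for _, r in subgroups.iterrows():
        rows.append(
            {
                "group": r["group"],
                "n": int(r["n"]),
                "prevalence": format_percent(r["screen_positive_rate"]),
                "reference_prevalence": format_percent(r["prevalence"]),
                **{name: format_percent(r[name]) for name in _METRIC_COLUMNS},
                "roc_area": "NA (zero denominator)"
                if np.isnan(r["roc_area_single"])
                else f"{round_half_up(r['roc_area_single'], 3):.3f}",
                "exploratory": bool(r["exploratory"]),
            }
        )
    return pd.DataFrame(rows)


def metrics_to_dict(m: DiagnosticMetrics) -> dict:
    out: dict = {
        "table": {"tp": m.table.tp, "fn": m.table.fn, "fp": m.table.fp, "tn": m.table.tn},
        "n": m.table.n,
        "prevalence": m.table.prevalence,
        "screen_positive_rate": m.table.screen_positive_rate,
        "roc_area_single": m.roc_area_single,
        "level": m.level,
    }
    for name in _METRIC_COLUMNS:
        est: Estimate = getattr(m, name)
        out[name] = {
            "value": est.value,
            "ci": [est.ci.lower, est.ci.upper] if est.ci else None,
            "note": est.note or None,
        }
    return out


def roc_to_frame(roc: RocAnalysis) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cutpoint": p.cutpoint,
                "sensitivity": p.sensitivity,
                "false_positive_rate": p.false_positive_rate,
                "specificity": p.specificity,
            }
            for p in roc.points
        ]
    )


def write_reports(
    out_dir: str | Path,
    metrics_by_cutpoint: Mapping[int, DiagnosticMetrics],
    roc: RocAnalysis | None = None,
    subgroups: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write table/JSON/ROC outputs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cut_tab = render_cutpoint_table(metrics_by_cutpoint)
    paths["cutpoint_table_csv"] = out_dir / "accuracy_by_cutpoint.csv"
    cut_tab.to_csv(paths["cutpoint_table_csv"], index=False)
    paths["cutpoint_table_json"] = out_dir / "accuracy_by_cutpoint.json"
    paths["cutpoint_table_json"].write_text(
        json.dumps(
            {str(c): metrics_to_dict(m) for c, m in metrics_by_cutpoint.items()}, indent=2
        )
    )
    if roc is not None:
        paths["roc_csv"] = out_dir / "roc_points.csv"
        roc_to_frame(roc).to_csv(paths["roc_csv"], index=False)
        paths["roc_json"] = out_dir / "roc.json"
        paths["roc_json"].write_text(
            json.dumps(
                {
                    "auc_empirical": roc.auc_empirical,
                    "selected_cutpoint": roc.selected_cutpoint,
                    "selection_rule": roc.selection_rule,
                },
                indent=2,
            )
        )
    if subgroups is not None:
        paths["subgroup_csv"] = out_dir / "accuracy_by_subgroup.csv"
        render_subgroup_table(subgroups).to_csv(paths["subgroup_csv"], index=False)
    return paths


def plot_roc(roc: RocAnalysis, path: str | Path) -> None:
    """Optional ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    frame = roc_to_frame(roc).sort_values("false_positive_rate")
    xs = [0, *frame["false_positive_rate"], 1]
    ys = [0, *frame["sensitivity"], 1]
    ax.plot(xs, ys, "o-", label=f"AUC = {roc.auc_empirical:.3f}")
    for p in roc.points:
        ax.annotate(f">= {p.cutpoint}", (p.false_positive_rate, p.sensitivity))
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
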