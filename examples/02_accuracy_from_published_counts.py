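"""Diagnostic accuracy of the screener from the published study counts.

The validation study reported rounded full-sample metrics at cutpoint 1
(n = 224, 117 reference-positives).  This script recovers the unique integer
2x2 table behind those rounded values, then recomputes every accuracy
statistic with exact 95% confidence intervals, the likelihood ratios, and
the ROC with cutpoint selection.
"""

import marsha_screen as ms
from marsha_screen.diagnostics import likelihood_ratios
from marsha_screen.report import format_estimate

table = ms.reconstruct_confusion_table(
    n=224, n_reference_positive=117,
    sensitivity=0.838, specificity=0.907, ppv=0.907, npv=0.836, accuracy=0.871,
)
print(f"reconstructed table: tp={table.tp} fn={table.fn} fp={table.fp} tn={table.tn}")
print(f"reference prevalence {table.prevalence:.1%}, "
      f"screen-positive rate {table.screen_positive_rate:.1%}\n")

m = ms.metrics(table)
for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
    print(f"{name:>12}: {format_estimate(getattr(m, name))}")
print(f"{'ROC area':>12}: {m.roc_area_single:.3f}  (single-cutpoint, (sens+spec)/2)")

lr = likelihood_ratios(table)
print(f"\nLR+ = {lr.lr_positive:.2f}: a positive screen multiplies the pre-test")
print("odds of past-year dating abuse roughly ninefold.")
print(f"LR- = {lr.lr_negative:.2f}; post-test odds after a positive screen: "
      f"{lr.post_test_odds_positive:.2f}")

# ROC over cutpoints, using the score distribution the published rows imply
pos_scores = [0] * 19 + [1] * 47 + [2] * 29 + [3] * 22
neg_scores = [0] * 97 + [1] * 10
roc = ms.roc_curve(pos_scores + neg_scores, [1] * 117 + [0] * 107)
print(f"\nROC points (cutpoint, sensitivity, FPR):")
for p in roc.points:
    print(f"  >= {p.cutpoint}: sens {p.sensitivity:.3f}, FPR {p.false_positive_rate:.3f}")
print(f"empirical (trapezoidal) AUC: {roc.auc_empirical:.3f}")
print(f"selected cutpoint ({roc.selection_rule}): {roc.selected_cutpoint}")
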