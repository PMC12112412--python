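"""Observed-vs-predicted evaluation statistics on a synthetic panel.

Aligns the observed and predicted records of a generated pearl-millet
panel and prints the usual crop-model evaluation report: RMSE (absolute
and normalized), MAE, signed bias, Willmott's index, the predicted-on-
observed regression, and Welch's test of the two means.
"""

import yieldstab as ys

panel = ys.generate_lte_panel(ys.preset_panel_config("sadore_millet", seed=7))
pairs = ys.align_observed_predicted(panel)
report = ys.evaluate_pairs(pairs)

print(f"n pairs           {report.n}")
print(f"mean obs / pred   {report.mean_obs:.3f} / {report.mean_pred:.3f} Mg/ha")
print(f"RMSE_a            {report.rmse_a:.3f} Mg/ha  (vs SD obs {report.sd_obs:.3f})")
print(f"RMSE_n            {report.rmse_n:.1f} %      (vs CV obs {report.cv_obs:.1f} %)")
print(f"MAE / bias        {report.mae:.3f} / {report.bias:+.3f} Mg/ha")
print(f"Willmott WI       {report.wi:.3f}  (1 = perfect)")
print(f"regression        E = {report.slope:.2f} O + {report.intercept:.2f}, r2 = {report.r2:.2f}")
print(f"Welch p           {report.p_welch:.2f}  (>= 0.05: means not distinguishable)")
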