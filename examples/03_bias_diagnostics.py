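"""Small-study bias diagnostics on clean and selectively published data.

Generates the same 20-study collection twice: once as drawn, and once with
null small studies suppressed (resampled until they lean the true way),
then runs Egger's regression and Begg's rank test on both.
"""

from metasynopsis import SimConfig, begg_test, egger_test, simulate_binary_meta

base = dict(
    k=20, theta=0.1, maf=0.3,
    n_cases_range=(25, 2500), n_controls_range=(25, 2500), seed=42,
)

for label, gamma in (("clean collection", 0.0), ("suppressed nulls", 1.0)):
    ds = simulate_binary_meta(SimConfig(bias_gamma=gamma, **base))
    intercept, se, egger_p = egger_test(ds)
    tau, begg_p, _ = begg_test(ds)
    print(f"{label}:")
    print(f"  Egger intercept {intercept:+.3f} (se {se:.3f}), p = {egger_p:.4f}")
    print(f"  Begg  Kendall tau {tau:+.3f},            p = {begg_p:.4f}")

print(
    "\nBoth tests are read at p < 0.10. A positive Egger intercept after "
    "suppression reflects the funnel asymmetry created when imprecise null "
    "studies go unpublished."
)
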