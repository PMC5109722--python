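"""Recalibration laws across epidemic parameters.

Sweeps several (R0_c, mu_c) points on one synthetic network, then fits the
linear recalibration laws R0_h = a*R0_c + b and mu_h = d*mu_c + e and the
epidemic-size power law alpha_h = a * alpha_c**b.  A scaled-down version of
the full experiment (fewer realizations, a subset of the nine-point grid) so
it finishes in a couple of minutes.
"""

from sirmix import (
    ContactModelParams,
    GroupStructure,
    fit_linear_law,
    fit_power_law,
    generate,
    pearson_with_ci,
    sweep,
)

groups = GroupStructure.equal_groups(3, 20)
net = generate(ContactModelParams(affinity_out=0.013), groups, seed=7)

points = [(1.1, 0.3456), (2.1, 0.3456), (3.5, 0.3456),
          (1.4, 0.1728), (1.4, 0.8640)]
table = sweep(net, points=points, n_real=500, n_real_fit=5000, n_reps_r0=1000, seed=11)
print(table[["r0_c", "mu_c", "r0_h", "mu_h", "alpha_c", "alpha_h"]].round(3))

at_mu = table[table.mu_c == 0.3456]
law_r0 = fit_linear_law(at_mu.r0_c, at_mu.r0_h)
print(f"\nR0_h = {law_r0.slope:.2f} * R0_c + {law_r0.intercept:.2f}"
      f"  (slope se {law_r0.slope_se:.2f})")

at_r0 = table[table.r0_c == 1.4]
law_mu = fit_linear_law(at_r0.mu_c, at_r0.mu_h)
print(f"mu_h = {law_mu.slope:.2f} * mu_c + {law_mu.intercept:.2f}"
      f"  (slope se {law_mu.slope_se:.2f})")

a, b, se_a, se_b = fit_power_law(table.alpha_c, table.alpha_h)
print(f"alpha_h = {a:.2f} * alpha_c^{b:.2f}  (se {se_a:.2f}, {se_b:.2f})")

r, lo, hi, p = pearson_with_ci(table.d_P, table.d_T)
print(f"corr(Delta_P, Delta_T): r = {r:.2f} [{lo:.2f}, {hi:.2f}], p = {p:.2g}")
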