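"""Cross-lab permutation test and its power analysis.

Generates one feature value per mouse for 10 labs x 4 mice under the null
(labs exchangeable) and under an alternative in which one lab is shifted,
runs the max-CDF-distance permutation test on both, and then asks — via
binary search on a frozen permutation null — how far a lab's values would
have to shift before the test turns significant.
"""

from reprophys import gen_lab_feature_values, permutation_test, power_shift

# Null: every mouse's value drawn from the same distribution.
values, labels = gen_lab_feature_values(10, 4, seed=0)
res = permutation_test(values, labels, n_perm=10000, seed=0)
print(f"null data:    max-CDF distance = {res.statistic:.3f}, p = {res.p_value:.3f}")

# Alternative: lab_02 shifted by three pooled SDs.
values2, labels2 = gen_lab_feature_values(10, 4, seed=0, lab_shifts={2: 3.0})
res2 = permutation_test(values2, labels2, n_perm=10000, seed=0)
print(f"shifted lab:  max-CDF distance = {res2.statistic:.3f}, p = {res2.p_value:.4f}")
print("significance uses the stringent alpha = 0.01 convention\n")

# Power analysis: smallest shift of lab_05 that reaches significance.
ps = power_shift(values, labels, "lab_05", n_perm=5000, seed=0)
print(
    f"power analysis for lab_05: shift up {ps.shift_up:+.3f}, "
    f"shift down {ps.shift_down:+.3f} (tolerance {ps.tol:.4f})"
)
print(
    "\nThe permissible-shift interval quantifies the test's sensitivity:"
    "\nany displacement of that lab beyond these bounds would be detected"
    "\nas a reproducibility failure at alpha = 0.01."
)
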