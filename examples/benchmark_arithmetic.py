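"""Accounting identities of the reference 3,883-drug ATC benchmark.

The published summary tables of the benchmark are internally redundant:
the class-multiplicity breakdown and the 14 per-class sizes must count the
same virtual-drug total, and the overall two-order success rate L_2 is
determined by the order-1/order-2 accuracies and the exact AN.  This
script recomputes those identities with the package's accounting
functions.
"""

from atcpred import MultiplicityHistogram, choose_m, lm_from_order_accuracies, virtual_count
from atcpred.synthetic import (
    BENCHMARK_CLASS_SIZES,
    BENCHMARK_MULTIPLICITY,
    COMPARISON_MULTIPLICITY,
)


def hist(breakdown):
    return MultiplicityHistogram({k + 1: c for k, c in enumerate(breakdown)})


bench = hist(BENCHMARK_MULTIPLICITY)
print(
    f"full benchmark: {bench.structural_count} drugs -> "
    f"{virtual_count(bench)} virtual (class sizes sum to {sum(BENCHMARK_CLASS_SIZES)})"
)

comp = hist(COMPARISON_MULTIPLICITY)
an = virtual_count(comp) / comp.structural_count
print(
    f"comparison subset: {comp.structural_count} drugs -> {virtual_count(comp)} virtual, "
    f"AN = {an:.4f} (rounds to {round(an, 2)}), m = {choose_m(an)}"
)

for name, ac12, h in [
    ("interaction-based", (0.6740, 0.2109), comp),
    ("similarity-based", (0.4036, 0.1389), comp),
    ("integrated", (0.7255, 0.2011), bench),
]:
    a = virtual_count(h) / h.structural_count
    l2 = lm_from_order_accuracies(ac12, a, m=2)
    print(f"{name:>18}: L_2 = (AC_1 + AC_2)/AN = {100 * l2:.2f}%")
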