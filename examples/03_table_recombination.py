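"""Recombine stage-level per-class accuracies into final cascade accuracies.

In the asymmetric cascade, G2G3 calls terminate at stage 1 while E/G1
calls are resolved by stage 2, so final per-class accuracies are products
of stage fractions; the final mean is their class-count-weighted average.
Printed percentages encode integer correct counts (83.3% of 24 is 20/24),
which the default rounding mode reconstructs before combining.
"""

from ramangrade import aggregate_final_accuracy

counts = dict(n_E=31, n_G1=24, n_G2G3=99)

print("full cascade (stage-1 100/100, stage-2 100/83.3):")
print(aggregate_final_accuracy(100.0, 100.0, 100.0, 83.3, **counts).to_table())

print("\nPCA+SVM pipeline variant (stage-1 60.0/82.8, stage-2 100/4.2):")
print(aggregate_final_accuracy(60.0, 82.8, 100.0, 4.2, **counts).to_table())

print("\nPCA+LDA pipeline variant (stage-1 67.3/100, stage-2 100/4.2):")
print(aggregate_final_accuracy(67.3, 100.0, 100.0, 4.2, **counts).to_table())
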