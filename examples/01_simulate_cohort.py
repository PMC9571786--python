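"""Generate a synthetic chondrogenic-tumor Raman cohort and inspect it.

The simulator plants the grade-dependent biochemistry of cartilaginous
tumors (collagen/chondroitin degradation, G1 calcification, rising DNA/RNA
signal) on top of fluorescence, a Rayleigh tail, patient variability and
noise, with the 400-spectrum / patient-disjoint split structure of the
study design.
"""

import numpy as np

from ramangrade import CohortConfig, generate_cohort, write_spectra_table
from ramangrade.simulate import split_by_meta

cohort = generate_cohort(CohortConfig(), seed=7)
train, test = split_by_meta(cohort)

print(f"total spectra: {len(cohort)} on a {len(cohort.shared_grid)}-point grid "
      f"({cohort.shared_grid[0]:.0f}-{cohort.shared_grid[-1]:.0f} cm^-1)")
for name, split in (("train", train), ("test", test)):
    counts = {c: int(np.sum(split.labels() == c)) for c in ("E", "G1", "G2G3")}
    print(f"{name}: {counts}, patients {sorted(map(str, set(split.patient_ids())))}")
# the two splits share no patient: the one-patient-per-class-out design
assert not set(train.patient_ids()) & set(test.patient_ids())

write_spectra_table(cohort, "cohort.csv", "wide_rows", metadata="cohort_meta.csv")
print("wrote cohort.csv + cohort_meta.csv")
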