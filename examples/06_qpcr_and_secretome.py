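"""ΔΔCT fold changes and cytokine-array normalization.

A Ct table is planted with VEGFA up 2× in EC:PC and 4× in EC:PC:AC
cocultures at day 7 (relative to day-0 EC, CD31 reference gene); the
ΔΔCT method must cancel per-sample loading offsets and recover the
folds.  A two-membrane cytokine array with different exposure factors
shows reference-spot normalization cancelling exposure exactly.
"""

from nichequant.assays import (
    ddct_fold_change,
    normalize_spots,
    secretome_fold_change,
)
from nichequant.synth import make_ct_table, make_spot_array

folds = {"VEGFA": {("EC:PC", 7): 2.0, ("EC:PC:AC", 7): 4.0}}
table, _ = make_ct_table(folds, noise_sd=0.1, sample_shift_sd=0.5, seed=0)
fc = ddct_fold_change(table, "VEGFA", reference_gene="CD31", baseline=("EC", 0))
print("VEGFA fold changes vs day-0 EC (CD31 reference):")
print(fc.to_string(index=False))

values = {"IL8": {"GBM": 1.0, "EC": 2.5}, "VEGF": {"GBM": 2.0, "EC": 1.0}}
groups = {"m1": "GBM", "m2": "EC"}
spots, smap, truth = make_spot_array(
    values, groups, exposure_factors={"m1": 0.4, "m2": 3.1}, seed=0
)
norm = normalize_spots(spots, smap)
sec = secretome_fold_change(norm, groups, baseline_group="GBM")
print("\nsecretome fold change vs GBM group "
      "(membranes exposed at 0.4× and 3.1×):")
print(sec.to_string(index=False))
print()
print("Fold changes land on the planted 2× and 4× despite ±0.5-cycle "
      "loading offsets, and the 8-fold exposure difference between "
      "membranes cancels exactly under reference-spot normalization.")
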