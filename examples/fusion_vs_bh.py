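"""Fusion scoring versus BH-adjusted moderated t on a training contrast.

With 8 participants per training group, individual-protein training
responses of moderate size rarely survive BH adjustment, while the
fold-change x significance fusion score (sign-flip permutation null)
calls many more proteins — the trade-off between error control and
sensitivity at single-fibre sample sizes.
"""

from fibretmt.diffexpr import (
    bh_adjust, eb_moderate, fit_linear_models, fusion_scheme, paired_design,
    paired_differences, training_contrast_samples,
)
from fibretmt.normalise import log2_transform
from fibretmt.simulate import CohortParams, generate_cohort

params = CohortParams(
    n_proteins=800, frac_fibre_de=0.0,
    frac_train_de=0.15, train_effect_sd=0.35,
    batch_location_sd=0.0, batch_scale_log_sd=0.0, loading_log2_sd=0.0,
    missing_intercept=-50.0, missing_random_rate=0.0,
)
matrix, samples, *_ = generate_cohort(params, seed=10)
logged = log2_transform(matrix)

cell = training_contrast_samples(samples, "MICT", "I")
sub = logged.subset_samples(list(cell["sample_id"]))
cond = cell.set_index("sample_id")["timepoint"]

diffs = paired_differences(sub, cell, cond, "POST")
fusion = fusion_scheme(diffs, seed=1)
fit = eb_moderate(fit_linear_models(sub, paired_design(cell, cond, "POST")))

n_fusion = int((fusion["fusion_p"] < 0.05).sum())
n_raw = int((fit.p < 0.05).sum())
n_bh = int((bh_adjust(fit.p) < 0.05).sum())

print(f"proteins analysed: {len(fusion)} "
      f"(15% carry a true ~0.35 log2 training effect)")
print(f"unadjusted moderated-t p < 0.05: {n_raw}")
print(f"BH-adjusted p < 0.05:            {n_bh}")
print(f"fusion significance < 0.05:      {n_fusion}")
print("\nThe fusion scheme sits between the unadjusted and BH counts: it")
print("recovers moderate effects BH discards, at a looser error guarantee.")
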