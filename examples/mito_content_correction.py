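"""The mitochondrial-content confound, created and removed.

A cohort is simulated in which type I fibres carry exactly twice the
mitochondrial content of type II fibres and *no* mitochondrial protein is
individually remodelled. Naive differential expression then flags nearly
every mitochondrial protein; re-normalising the mitochondrial subset on
its own (same SL -> TMM -> log2 -> ComBat chain) removes the shared
content signal, leaving the nominal false-positive rate.
"""

import numpy as np

from fibretmt.diffexpr import (
    de_table, eb_moderate, fibre_contrast_samples, fit_linear_models,
    paired_design,
)
from fibretmt.io import RAW
from fibretmt.mitonorm import mito_renormalise
from fibretmt.normalise import log2_transform, normalise_chain
from fibretmt.preprocess import filter_missing, knn_impute
from fibretmt.simulate import generate_cohort, null_params, with_mito_content

params = with_mito_content(
    null_params(
        n_participants_per_group=8, n_proteins=1000,
        batch_location_sd=0.30, batch_scale_log_sd=0.10,
        loading_log2_sd=0.20, missing_intercept=5.0,
        missing_slope=-0.5, missing_random_rate=0.005,
    ),
    type_i=2.0,
)
matrix, samples, proteins, _ = generate_cohort(params, seed=23)
filtered, _ = filter_missing(matrix)
imputed = knn_impute(log2_transform(filtered))
complete_raw = imputed.with_data(np.exp2(imputed.data), scale=RAW)


def fibre_de(m):
    pre = fibre_contrast_samples(samples, "PRE")
    sub = m.subset_samples(list(pre["sample_id"]))
    cond = pre.set_index("sample_id")["fibre_type"]
    return de_table(eb_moderate(fit_linear_models(
        sub, paired_design(pre, cond, "II"))))


normalised, *_ = normalise_chain(complete_raw, samples)
mito_ids = set(proteins.loc[proteins["is_mitochondrial"], "protein_id"])
before = fibre_de(normalised)
before = before[before["protein_id"].isin(mito_ids)]

corrected, *_ = mito_renormalise(complete_raw, proteins, samples)
after = fibre_de(corrected)

print(f"mitochondrial proteins analysed: {len(after)}")
print(f"significant with standard normalisation:  "
      f"{int(before['significant'].sum())} "
      f"({100 * before['significant'].mean():.1f}%)")
print(f"significant after content correction:     "
      f"{int(after['significant'].sum())} "
      f"({100 * after['significant'].mean():.1f}%)")
print("\nAll planted signal was a global 2x content multiplier, so every")
print("call under standard normalisation is a content artefact; the")
print("corrected analysis returns to the nominal error rate.")
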