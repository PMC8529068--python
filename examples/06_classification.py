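"""Disease classification by repeated down-sampled cross-validation.

5-repeat 10-fold stratified CV; within each training fold the majority
class is subsampled to the minority size before fitting the random forest
(test folds untouched).  The AUC contrast shows where the disease signal
lives: in the biomarkers, not the microbiome.
"""

from trinetomics import (CohortConfig, CvScheme, OmicsMatrix, default_classifier,
                         generate_cohort, repeated_cv)

mgs, met, phe, truth = generate_cohort(CohortConfig(seed=0))
bio = OmicsMatrix(phe.data.drop(columns=["disease"]), "phenotype")
y = phe.data["disease"]

scheme = CvScheme(k=10, repeats=5, downsample=True, seed=0)
for name, matrix in (("biomarkers", bio), ("microbiome", mgs)):
    res = repeated_cv(matrix, y, scheme, default_classifier(0, 300))
    per_rep = ", ".join(f"{v:.2f}" for v in res.per_repeat)
    print(f"{name:11s} AUC = {res.aggregate:.3f}  (per repeat: {per_rep})")
    print(f"            top predictors: "
          f"{', '.join(res.importances.sort_values(ascending=False).index[:3])}")
# The biomarker model beats the microbiome model because the label is
# driven by factor-free biomarkers; the microbiome AUC fluctuates around
# chance (at n = 138 a single cohort draw can sit a few points above 0.5).
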