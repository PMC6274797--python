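"""Evaluate recovery of held-out associations on planted-block data.

Generates the default synthetic dataset, runs LOOCV and five-fold
cross-validation (rebuilding the GIP kernels and the thresholded network
per fold), and reports ROC AUC -- the probability that a held-out true
association outranks a random unknown pair.
"""

import pwcda

data = pwcda.generate()  # default planted-block spec, seed 7
table = data.table
print(
    f"dataset: {table.n_circ} circRNAs, {table.n_diseases} diseases, "
    f"{table.n_pairs} verified associations"
)

loocv = pwcda.loocv(data.table, data.circ_catalog, data.disease_catalog)
print(f"LOOCV AUC = {loocv.auc:.4f} ({len(loocv.skipped_diseases)} diseases skipped)")

fivefold = pwcda.kfold_cv(
    data.table, data.circ_catalog, data.disease_catalog, k=5, seed=42
)
print(f"five-fold AUC (seed 42) = {fivefold.auc:.4f}")

print(
    "AUC well above 0.5 means the path-weighted scores recover the planted\n"
    "block structure: held-out associations rank above unknown pairs even\n"
    "though each was removed from its own training network."
)
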