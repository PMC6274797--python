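"""Fuse Jaccard annotation similarity with the GIP kernel.

Generates a small planted-block dataset, computes the circRNA Jaccard
(semantic) similarity and the GIP kernel on association profiles, and
shows how fusion fills the zero entries the sparse annotations leave --
including entities with no annotations at all.
"""

import numpy as np

import pwcda

spec = pwcda.SyntheticSpec(n_circ=16, n_dis=8, empty_annotation_frac=0.25, seed=11)
data = pwcda.generate(spec)
table = data.table

m = pwcda.build_association_matrix(table)
cs = pwcda.annotation_similarity_matrix(data.circ_catalog, table.circ_ids, "semantic")
kc = pwcda.gip_kernel_matrix(m, "circrna")
ics = pwcda.integrate_similarity(cs, kc)

def offdiag_density(values):
    off = values[~np.eye(len(values), dtype=bool)]
    return (off > 0).mean()

print(f"{table.n_circ} circRNAs, {table.n_diseases} diseases, {table.n_pairs} associations")
print(f"Jaccard similarity off-diagonal density:    {offdiag_density(cs.values):.2f}")
print(f"GIP kernel off-diagonal density:            {offdiag_density(kc.values):.2f}")
print(f"integrated similarity off-diagonal density: {offdiag_density(ics.values):.2f}")

unannotated = [c for c in table.circ_ids if not data.circ_catalog.terms(c)]
if unannotated:
    c = unannotated[0]
    j = table.circ_ids.index(c)
    partner = 1 - j if j < 2 else 0
    print(
        f"{c} has no annotations: Jaccard row is all zero "
        f"(e.g. CS={cs.values[j, partner]:.3f} vs {table.circ_ids[partner]}), "
        f"so fusion takes its GIP value KC={kc.values[j, partner]:.3f} -> "
        f"ICS={ics.values[j, partner]:.3f}"
    )
print(
    "Fusion keeps every non-zero Jaccard score and falls back to the\n"
    "association-profile kernel elsewhere, so no entity is left without\n"
    "a similarity neighborhood."
)
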