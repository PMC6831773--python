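"""Estimate an OTU's band center when only half the fractions were sequenced.

RNA-SIP studies often sequence a subset of gradient fractions.  The sparse
estimator assumes the OTU's density distribution is Gaussian with a standard
deviation fixed at the value fitted to the bulk RNA concentration profile,
and finds the band center on a fine density grid.  Here we simulate a full
16-fraction gradient, hide every other fraction, and compare the two
estimators for a few taxa.
"""

import numpy as np

from sipshift.density import fit_gradient_profile, mean_bd_sparse, weighted_mean_bd
from sipshift.model import Assay, Isotope, OtuFractionTable, Treatment
from sipshift.simulate import DesignSpec, default_community, simulate_gradient

taxa = default_community()
design = DesignSpec(rna_sequenced=16)
full = simulate_gradient(
    taxa, design, Treatment.NH4, Isotope.C12, Assay.RNA, seed=12
)

idx = list(range(0, design.n_fractions, 2))
sparse = OtuFractionTable(
    full.otu_ids, [full.samples[j] for j in idx], full.counts[:, idx]
)
profile = fit_gradient_profile(
    sparse.densities, np.array([x.na_concentration for x in sparse.samples])
)
print(
    f"Bulk RNA profile: mu={profile.fitted_mu:.4f} g/ml, "
    f"sigma={profile.fitted_sigma:.4f} g/ml"
)

print(f"{'OTU':10s} {'full-data mean':>14s} {'8-fraction est.':>15s} {'diff':>8s}")
for taxon in taxa[::10]:
    dense = weighted_mean_bd(full, taxon.otu_id)
    est = mean_bd_sparse(sparse, taxon.otu_id, profile)
    print(f"{taxon.otu_id:10s} {dense:14.4f} {est:15.4f} {est - dense:8.4f}")
print("\nDifferences stay within a few thousandths of a g/ml — small against")
print("the ~0.036 g/ml shift that full 13C labeling produces.")
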