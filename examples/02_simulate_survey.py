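"""Generate a synthetic vineyard weed survey and inspect its structure.

The default design mirrors a 46-plot, 30-species, 7-year presence-absence
survey with ~10% of plot-years unsurveyed and seed masses spanning
0.1-14.5 mg.  The generator returns both the dataset and the latent truth
(species coefficients, hidden seed-bank states) behind it.
"""

import numpy as np

from seedbankhmm import MISSING, DesignSpec, dataset_to_tables, generate_dataset

dataset, truth = generate_dataset(DesignSpec(seed=11))
panel, covariates, traits = dataset_to_tables(dataset)

observed = dataset.obs != MISSING
print(f"plots x species x years : {dataset.obs.shape}")
print(f"plot-year surveys       : {observed[:, 0, :].sum()} of {dataset.n_plots * dataset.n_years}")
print(f"overall occupancy       : {(dataset.obs == 1).sum() / observed.sum():.2%} of observed cells")
print(f"seed mass range (mg)    : {traits.table.seed_mass.min():.3f} - {traits.table.seed_mass.max():.2f}")
print(f"hidden seed banks year 1: {(truth['hidden_states'][:, :, 0] >= 1).mean():.2%} of plot x species")
print("\ncovariate table head:\n", covariates.table.head(3).round(2).to_string(index=False))
# The panel is a plain long-format CSV; the hidden states exist only in the
# truth record, exactly the quantity the model must infer in real surveys.
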