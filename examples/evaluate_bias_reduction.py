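"""Show that the simulated-null p-values remove study bias from the scores.

Builds a maximally study-biased dataset (bias_strength = 1: well-studied
genes get both more interactions and more annotations), runs the method
with and without the simulated null for a panel of query diseases, and
prints the Spearman correlation of each variant's gene scores with network
degree and other data-availability features.
"""

import numpy as np

from phenorank import RunConfig
from phenorank.evaluation import bias_correlation_study
from phenorank.synthetic import SyntheticSpec, generate_dataset

dataset = generate_dataset(SyntheticSpec(bias_strength=1.0, rng_seed=0))

rng = np.random.default_rng(3)
catalogued = sorted(
    d for d in dataset.db.diseases
    if not d.startswith(("DP", "DS")) and dataset.db.diseases[d].term_ids
)
queries = [catalogued[i] for i in rng.choice(len(catalogued), 20, replace=False)]

tables = bias_correlation_study(
    dataset.db, dataset.network, dataset.ontology, queries,
    RunConfig(n_sets=200, rng_seed=5),
)

print("Spearman rho between gene scores and data-availability features")
print("(mean over 20 query diseases; simulation scores are -log10 p)\n")
print(f"{'feature':24} {'with null':>10} {'without null':>13}")
for feature in tables["simulation"].columns:
    print(
        f"{feature:24} {tables['simulation'][feature].mean():10.3f} "
        f"{tables['no_simulation'][feature].mean():13.3f}"
    )
print(
    "\nWithout the null, propagated scores track degree almost perfectly —"
    "\nwell-studied genes win regardless of the query. Comparing against"
    "\nsimulated phenotype-term sets cancels that advantage."
)
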