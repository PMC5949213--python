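"""Leave-one-out cross-validation on planted disease-gene associations.

Masks each planted association in turn, reruns the prioritization with the
disease as query, and measures how well the masked gene is recovered —
pooled into a ROC AUC. Also runs the human-only and mouse-only ablations to
show that integrating both species helps.
"""

from phenorank import RunConfig
from phenorank.evaluation import loo_cross_validation
from phenorank.synthetic import SyntheticSpec, generate_dataset

dataset = generate_dataset(SyntheticSpec(rng_seed=0))
print(f"{len(dataset.ground_truth)} planted associations, "
      f"{dataset.network.n} genes in the network\n")

for mode in ("both", "human_only", "mouse_only"):
    trials, auc = loo_cross_validation(
        dataset.db, dataset.network, dataset.ontology,
        RunConfig(n_sets=200, rng_seed=2, species_mode=mode),
        dataset.ground_truth,
    )
    mean_rank = sum(t.masked_gene_rank for t in trials) / len(trials)
    print(f"species data = {mode:11}: AUC {auc:.3f} "
          f"(masked gene mean rank {mean_rank:.1f} of {trials[0].n_eligible})")

print(
    "\nAUC is the probability that a masked causal gene outscores a random"
    "\nnon-associated gene; 0.5 is chance. Using human disease and mouse"
    "\nmutant phenotypes together recovers planted genes at least as well"
    "\nas either species alone."
)
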