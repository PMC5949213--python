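"""Compare disease phenotype-term sets with simGIC semantic similarity.

Builds a tiny hand-written ontology and three diseases, computes the
information content of every term from the annotation corpus, and prints
the pairwise IC-weighted Jaccard (simGIC) similarities.
"""

from phenorank import compute_ic, parse_obo, sim_gic

OBO = """format-version: 1.2

[Term]
id: PH:0
name: phenotypic abnormality

[Term]
id: PH:1
name: immune abnormality
is_a: PH:0

[Term]
id: PH:2
name: antibody deficiency
is_a: PH:1

[Term]
id: PH:3
name: IgM deficiency
is_a: PH:2

[Term]
id: PH:4
name: IgE deficiency
is_a: PH:2

[Term]
id: PH:5
name: dementia
is_a: PH:0
"""

ontology = parse_obo(OBO)
diseases = {
    "immunodeficiency_A": {"PH:3"},          # IgM deficiency
    "immunodeficiency_B": {"PH:4"},          # IgE deficiency
    "neurodegeneration":  {"PH:5"},          # dementia
}
compute_ic(ontology, list(diseases.items()))

print("pairwise simGIC (0 = unrelated, 1 = identical annotations):\n")
names = list(diseases)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        s = sim_gic(diseases[a], diseases[b], ontology)
        print(f"  {a:18} vs {b:18}: {s:.3f}")

print(
    "\nThe two immunodeficiencies share the informative ancestor"
    "\n'antibody deficiency', so they are similar; dementia shares only the"
    "\nuninformative root (IC 0) and scores 0."
)
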