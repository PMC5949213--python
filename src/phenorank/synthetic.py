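"""Seeded synthetic ontologies, annotation corpora and PPI networks.

Everything the prioritization method consumes — a rooted is_a DAG of
phenotype terms, a corpus of annotated "diseases" and "mouse mutants" with
gene associations and orthology, and a skewed-degree PPI network — can be
generated here, offline and reproducibly.

Two design features matter:

* a latent per-gene *study intensity* can be coupled (via ``bias_strength``)
  to both a gene's network degree and its number of phenotype associations,
  emulating study bias: well-studied genes accumulate more recorded
  interactions and more curated annotations.  At ``bias_strength = 0`` the
  network grows by plain preferential attachment and associations are drawn
  uniformly, so degree and intensity decouple.
* diseases and mutants draw their term sets from shared depth-biased term
  clusters, so phenotypically related sources share terms and the
  co-annotation structure needed by the simulated-null sampler exists.

Planted disease modules provide recoverable ground truth for
cross-validation: a connected set of genes whose associated diseases (and
mouse mutants) are annotated from one common term pool.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .annotations import AssociationDB, PhenotypeSource, build_coannotation_counts
from .network import PPINetwork
from .ontology import Ontology, Term, compute_ic, write_obo

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_ontology",
    "draw_study_intensity",
    "generate_corpus",
    "generate_network",
    "plant_disease_modules",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator; defaults give a small but complete dataset.

    ``bias_strength`` in [0, 1] couples the latent study intensity to both
    network attachment and association multiplicity; 0 means unbiased data,
    1 means degree and annotation counts are driven by intensity alone.
    """

    n_terms: int = 300
    dag_max_parents: int = 2
    n_diseases: int = 150
    n_mutants: int = 80
    terms_per_source: tuple[int, int] = (3, 10)
    n_clusters: int = 12
    cluster_fidelity: float = 0.8
    n_genes: int = 200
    edges_per_gene: int = 2
    associations_per_gene: float = 1.25
    bias_strength: float = 0.0
    n_planted_modules: int = 2
    module_size: int = 5
    module_term_pool: int = 15
    module_support_diseases: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2 or self.n_genes < 2:
            raise ValueError("n_terms and n_genes must be >= 2")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """A complete generated dataset, ready to run (IC and co-counts built)."""

    spec: SyntheticSpec
    ontology: Ontology
    db: AssociationDB
    network: PPINetwork
    study_intensity: dict[str, float]
    ground_truth: list[tuple[str, str]] = field(default_factory=list)


def _term_id(i: int) -> str:
    return f"PT:{i:07d}"


def generate_ontology(spec: SyntheticSpec, rng: np.random.Generator) -> Ontology:
    """Single-rooted random DAG: term i draws 1-2 parents among terms < i."""
    terms: dict[str, Term] = {_term_id(0): Term(_term_id(0), "root")}
    for i in range(1, spec.n_terms):
        n_parents = int(rng.integers(1, spec.dag_max_parents + 1))
        n_parents = min(n_parents, i)
        parents = rng.choice(i, size=n_parents, replace=False)
        terms[_term_id(i)] = Term(
            _term_id(i),
            f"synthetic phenotype {i}",
            frozenset(_term_id(int(p)) for p in parents),
        )
    return Ontology(terms)


def gene_ids_for(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def draw_study_intensity(
    spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, float]:
    """Latent per-gene study intensity, heavy-tailed (log-normal)."""
    values = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    return dict(zip(gene_ids_for(spec), values.tolist()))


def _depth_weights(ontology: Ontology, rng: np.random.Generator) -> tuple[list, np.ndarray]:
    term_ids = ontology.live_term_ids
    depths = np.array([ontology.max_depth(t) for t in term_ids], dtype=float)
    weights = depths + 0.5  # deeper (more specific) terms annotate more often
    return term_ids, weights / weights.sum()


def _sample_term_set(
    pool: list[str],
    all_terms: list[str],
    size: int,
    fidelity: float,
    rng: np.random.Generator,
) -> frozenset[str]:
    n_pool = min(int(rng.binomial(size, fidelity)), len(pool))
    chosen = set(rng.choice(pool, size=n_pool, replace=False)) if n_pool else set()
    outside = [t for t in all_terms if t not in chosen]
    n_rest = min(size - len(chosen), len(outside))
    if n_rest > 0:
        chosen |= set(rng.choice(outside, size=n_rest, replace=False))
    return frozenset(str(t) for t in chosen)


def generate_corpus(
    spec: SyntheticSpec,
    ontology: Ontology,
    rng: np.random.Generator,
    study_intensity: dict[str, float] | None = None,
) -> AssociationDB:
    """Diseases, mutants, gene associations and 1:1 mouse orthology.

    Sources draw term sets from shared depth-biased clusters; gene ends of
    associations are sampled with weights that interpolate between uniform
    (bias 0) and study intensity (bias 1).
    """
    genes = gene_ids_for(spec)
    if study_intensity is None:
        study_intensity = draw_study_intensity(spec, rng)
    term_ids, term_p = _depth_weights(ontology, rng)

    pool_size = 3 * spec.terms_per_source[1]
    clusters = [
        [
            str(t)
            for t in rng.choice(
                term_ids, size=min(pool_size, len(term_ids)), replace=False, p=term_p
            )
        ]
        for _ in range(spec.n_clusters)
    ]

    db = AssociationDB()
    lo, hi = spec.terms_per_source

    def make_sources(prefix: str, kind: str, count: int) -> list[str]:
        ids = []
        for i in range(count):
            sid = f"{prefix}{i:04d}"
            pool = clusters[int(rng.integers(spec.n_clusters))]
            size = int(rng.integers(lo, hi + 1))
            terms = _sample_term_set(
                pool, term_ids, size, spec.cluster_fidelity, rng
            )
            source = PhenotypeSource(sid, kind, terms)
            (db.diseases if kind == "human_disease" else db.mutants)[sid] = source
            ids.append(sid)
        return ids

    disease_ids = make_sources("D", "human_disease", spec.n_diseases)
    mutant_ids = make_sources("M", "mouse_mutant", spec.n_mutants)

    b = spec.bias_strength
    intensity = np.array([study_intensity[g] for g in genes])
    gene_w = (1.0 - b) + b * intensity / intensity.mean()
    gene_w = gene_w / gene_w.sum()

    n_assoc = int(round(spec.associations_per_gene * spec.n_genes))
    seen: set[tuple[str, str]] = set()
    for _ in range(n_assoc):
        gene = genes[int(rng.choice(spec.n_genes, p=gene_w))]
        disease = disease_ids[int(rng.integers(spec.n_diseases))]
        if (gene, disease) in seen:
            continue
        seen.add((gene, disease))
        db.gene_to_diseases.setdefault(gene, set()).add(disease)

    # 1:1 orthology: mouse gene MGi <-> human gene Gi; mutants attach to a
    # mouse gene with the same intensity weighting.
    for mid in mutant_ids:
        gene = genes[int(rng.choice(spec.n_genes, p=gene_w))]
        db.gene_to_mutants.setdefault(gene, set()).add(mid)
    return db


def generate_network(
    spec: SyntheticSpec,
    gene_ids: list[str],
    study_intensity: dict[str, float],
    rng: np.random.Generator,
) -> PPINetwork:
    """Connected growth network with tunable intensity-degree coupling.

    Nodes are added in random order.  Study bias enters the growth rule
    twice, mirroring hypothesis-driven interaction screening: a new node
    brings m_i = max(1, round(m * ((1-b) + b * s_i / mean(s)))) edges (well
    studied genes are probed more often), and each edge attaches to an
    existing node with propensity (1 - b) * uniform + b * scaled intensity
    (well-studied genes are preferred as partners).  At b = 0 the graph is a
    uniform random recursive graph with exactly
    |E| = C(n0, 2) + m * (n - n0) edges, n0 = m + 1 seed nodes (a clique);
    in general |E| = C(n0, 2) + sum_i min(m_i, nodes already present).
    """
    b = spec.bias_strength
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    network = PPINetwork(gene_ids)
    m = spec.edges_per_gene
    n0 = min(m + 1, len(order))
    for i in range(n0):
        for j in range(i + 1, n0):
            network.add_edge(order[i], order[j])

    scale = float(np.mean(list(study_intensity.values())))
    for i in range(n0, len(order)):
        existing = order[:i]
        m_i = max(1, round(m * ((1.0 - b) + b * study_intensity[order[i]] / scale)))
        prop = np.array(
            [(1.0 - b) + b * study_intensity[g] / scale for g in existing]
        )
        prop = prop / prop.sum()
        targets = rng.choice(len(existing), size=min(m_i, i), replace=False, p=prop)
        for t in targets:
            network.add_edge(order[i], existing[int(t)])
    return network


def plant_disease_modules(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[AssociationDB, PPINetwork, list[tuple[str, str]]]:
    """Plant recoverable disease-gene modules; returns ground truth.

    Each module is a connected set of genes; every module gene gets one new
    ground-truth disease, ``module_support_diseases`` additional support
    disease(s), and one new mouse mutant, all annotated from the module's
    common term pool, so the planted sources are phenotypically coherent
    across both species and each species carries independent signal (a
    masked ground-truth association leaves the support disease and the
    mutant intact).  Ground truth lists one (disease_id, gene_id) pair per
    module gene.
    """
    if spec.module_size > spec.n_genes:
        raise ValueError("module_size exceeds n_genes")
    term_ids, term_p = _depth_weights(ontology, rng)
    genes = network.gene_ids
    extra_edges: list[tuple[str, str]] = []
    ground_truth: list[tuple[str, str]] = []
    lo, hi = spec.terms_per_source

    available = list(genes)
    for mod in range(spec.n_planted_modules):
        members_idx = rng.choice(len(available), size=spec.module_size, replace=False)
        members = [available[int(i)] for i in members_idx]
        available = [g for g in available if g not in members]
        # wire a random spanning path so the module is connected
        path = [members[int(i)] for i in rng.permutation(len(members))]
        extra_edges.extend(zip(path, path[1:]))

        pool = [
            str(t)
            for t in rng.choice(
                term_ids,
                size=min(spec.module_term_pool, len(term_ids)),
                replace=False,
                p=term_p,
            )
        ]
        for g in members:
            did = f"DP{mod:02d}_{g}"
            mid = f"MP{mod:02d}_{g}"
            size_d = int(rng.integers(lo, hi + 1))
            size_m = int(rng.integers(lo, hi + 1))
            db.diseases[did] = PhenotypeSource(
                did, "human_disease", _sample_term_set(pool, term_ids, size_d, 0.9, rng)
            )
            db.mutants[mid] = PhenotypeSource(
                mid, "mouse_mutant", _sample_term_set(pool, term_ids, size_m, 0.9, rng)
            )
            db.gene_to_diseases.setdefault(g, set()).add(did)
            db.gene_to_mutants.setdefault(g, set()).add(mid)
            ground_truth.append((did, g))
            for k in range(spec.module_support_diseases):
                sid = f"DS{mod:02d}_{k}_{g}"
                size_s = int(rng.integers(lo, hi + 1))
                db.diseases[sid] = PhenotypeSource(
                    sid,
                    "human_disease",
                    _sample_term_set(pool, term_ids, size_s, 0.9, rng),
                )
                db.gene_to_diseases.setdefault(g, set()).add(sid)

    planted_network = network.with_edges(extra_edges)
    return db, planted_network, ground_truth


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full, run-ready dataset (IC and co-counts precomputed)."""
    rng = np.random.default_rng(spec.rng_seed)
    ontology = generate_ontology(spec, rng)
    intensity = draw_study_intensity(spec, rng)
    db = generate_corpus(spec, ontology, rng, intensity)
    network = generate_network(spec, gene_ids_for(spec), intensity, rng)
    db, network, ground_truth = plant_disease_modules(
        db, network, ontology, spec, rng
    )
    corpus = [(s.id, s.term_ids) for s in db.diseases.values()] + [
        (s.id, s.term_ids) for s in db.mutants.values()
    ]
    compute_ic(ontology, corpus)
    build_coannotation_counts(db)
    return SyntheticDataset(
        spec=spec,
        ontology=ontology,
        db=db,
        network=network,
        study_intensity=intensity,
        ground_truth=ground_truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the dataset as the OBO/TSV fixture files the readers consume."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("ontology", "ontology.obo"),
        ("disease_terms", "disease_terms.tsv"),
        ("mutant_terms", "mutant_terms.tsv"),
        ("gene_disease", "gene_disease.tsv"),
        ("mutant_genes", "mutant_genes.tsv"),
        ("orthology", "orthology.tsv"),
        ("ppi_edges", "ppi_edges.tsv"),
        ("ground_truth", "ground_truth.tsv"),
    ]}

    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        write_obo(dataset.ontology, fh)

    def write_pairs(path: str, header: str, pairs: Iterable[tuple[str, str]]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")

    db = dataset.db
    write_pairs(
        paths["disease_terms"],
        "disease_id\tterm_id",
        [(s.id, t) for s in db.diseases.values() for t in s.term_ids],
    )
    write_pairs(
        paths["mutant_terms"],
        "mutant_id\tterm_id",
        [(s.id, t) for s in db.mutants.values() for t in s.term_ids],
    )
    write_pairs(
        paths["gene_disease"],
        "gene_id\tdisease_id",
        [(g, d) for g, ds in db.gene_to_diseases.items() for d in ds],
    )
    # orthology is 1:1 by construction: mouse gene "MG_<gene>" per human gene
    write_pairs(
        paths["mutant_genes"],
        "mutant_id\tmouse_gene_id",
        [(m, f"MG_{g}") for g, ms in db.gene_to_mutants.items() for m in ms],
    )
    write_pairs(
        paths["orthology"],
        "mouse_gene_id\thuman_gene_id",
        [(f"MG_{g}", g) for g in dataset.network.gene_ids],
    )
    write_pairs(paths["ppi_edges"], "gene_a\tgene_b", dataset.network.edges)
    write_pairs(paths["ground_truth"], "disease_id\tgene_id", dataset.ground_truth)
    return paths
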