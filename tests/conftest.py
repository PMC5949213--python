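import io

import numpy as np
import pytest

from phenorank.annotations import build_coannotation_counts, load_corpus
from phenorank.ontology import compute_ic, parse_obo
from phenorank.synthetic import SyntheticSpec, generate_dataset

DIAMOND_OBO = """format-version: 1.2

[Term]
id: T:root
name: root

[Term]
id: T:b
name: b
is_a: T:root

[Term]
id: T:c
name: c
is_a: T:root

[Term]
id: T:a
name: a
is_a: T:b
is_a: T:c
"""


@pytest.fixture
def diamond_ontology():
    """a -> {b, c} -> root: the smallest multi-parent DAG."""
    return parse_obo(DIAMOND_OBO)


def _tsv(rows):
    return io.StringIO("".join(f"{a}\t{b}\n" for a, b in rows))


@pytest.fixture
def toy_db():
    """Three diseases d1={a,b,c}, d2={a,b}, d3={c,d}; two mutants; 3 genes.

    g1 is associated with d1 and d2; g2 with d3; mutant m1 maps (via mouse
    gene mgA) to both g1 and g3 (one-to-many orthology), m2 maps to g2.
    """
    db = load_corpus(
        disease_terms=_tsv(
            [("d1", "a"), ("d1", "b"), ("d1", "c"),
             ("d2", "a"), ("d2", "b"), ("d3", "c"), ("d3", "d")]
        ),
        mutant_terms=_tsv([("m1", "a"), ("m1", "d"), ("m2", "b")]),
        gene_disease=_tsv([("g1", "d1"), ("g1", "d2"), ("g2", "d3")]),
        mutant_genes=_tsv([("m1", "mgA"), ("m2", "mgB")]),
        orthology=_tsv([("mgA", "g1"), ("mgA", "g3"), ("mgB", "g2")]),
    )
    return build_coannotation_counts(db)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic fixture (unbiased; 200 genes, 2 planted modules)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def biased_dataset():
    """Fully study-biased fixture: degree and annotations track intensity."""
    return generate_dataset(SyntheticSpec(bias_strength=1.0))


def random_small_ontology(rng: np.random.Generator, max_terms: int = 30):
    """A small random DAG ontology plus a random annotation corpus with IC."""
    n_terms = int(rng.integers(4, max_terms + 1))
    spec = SyntheticSpec(n_terms=n_terms, rng_seed=int(rng.integers(2**31)))
    from phenorank.synthetic import generate_ontology

    onto = generate_ontology(spec, np.random.default_rng(spec.rng_seed))
    term_ids = onto.live_term_ids
    n_sources = int(rng.integers(2, 9))
    corpus = []
    for s in range(n_sources):
        k = int(rng.integers(1, max(2, n_terms // 2)))
        terms = set(
            str(t) for t in rng.choice(term_ids, size=min(k, len(term_ids)), replace=False)
        )
        corpus.append((f"s{s}", terms))
    compute_ic(onto, corpus)
    return onto, corpus


def random_term_set(rng: np.random.Generator, ontology, max_size: int = 6):
    terms = ontology.live_term_ids
    k = int(rng.integers(1, max_size + 1))
    return frozenset(
        str(t) for t in rng.choice(terms, size=min(k, len(terms)), replace=False)
    )
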