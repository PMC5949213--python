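"""Phenotype annotation corpus: diseases, mouse mutants, gene associations.

Holds the two kinds of phenotype source — human diseases and mouse mutants —
each with its set of phenotype-ontology terms, together with the gene-level
indexes the scorer needs: Y_i, the diseases associated with gene i, and Z_i,
the mutants of mouse genes orthologous to gene i.  Also builds the
term-by-term co-annotation counts over disease term sets that drive the
simulated phenotype-term null.

All identifiers are opaque strings; input tables are two-column TSV files
(an optional header line starts with '#').
"""

from __future__ import annotations

import copy
import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import numpy as np
from scipy import sparse

from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSource",
    "AssociationDB",
    "load_corpus",
    "build_coannotation_counts",
    "mask_association",
]

PathOrStream = Union[str, IO[str]]


@dataclass(frozen=True)
class PhenotypeSource:
    """A human disease or mouse mutant with its raw phenotype-term set W_i."""

    id: str
    kind: str  # "human_disease" | "mouse_mutant"
    term_ids: frozenset[str]


@dataclass
class AssociationDB:
    """Annotation corpus and gene-level association indexes.

    ``coannotation`` is populated by :func:`build_coannotation_counts`; it
    stores, for every ordered pair of terms, the number of diseases whose raw
    (non-closure-expanded) term set contains both.
    """

    diseases: dict[str, PhenotypeSource] = field(default_factory=dict)
    mutants: dict[str, PhenotypeSource] = field(default_factory=dict)
    gene_to_diseases: dict[str, set[str]] = field(default_factory=dict)
    gene_to_mutants: dict[str, set[str]] = field(default_factory=dict)
    # (term ids in fixed order, index map, symmetric CSR count matrix)
    coannotation: tuple[list[str], dict[str, int], sparse.csr_matrix] | None = None

    @property
    def has_coannotation(self) -> bool:
        return self.coannotation is not None

    def coannotation_count(self, term_a: str, term_b: str) -> int:
        """Number of diseases annotated with both terms (raw term sets)."""
        if self.coannotation is None:
            raise ValueError("co-annotation counts not built")
        _, index, mat = self.coannotation
        ia, ib = index.get(term_a), index.get(term_b)
        if ia is None or ib is None:
            return 0
        return int(mat[ia, ib])

    def genes(self) -> list[str]:
        """All genes with at least one disease or mutant association."""
        return sorted(set(self.gene_to_diseases) | set(self.gene_to_mutants))


def _read_pairs(source: PathOrStream, name: str) -> list[tuple[str, str]]:
    """Read a two-column TSV; '#'-prefixed lines are comments/headers."""

    def parse(handle: IO[str]) -> list[tuple[str, str]]:
        pairs = []
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                raise ValueError(
                    f"{name}: malformed row at line {lineno}: expected 2 "
                    f"tab-separated columns, got {len(row)}"
                )
            pairs.append((row[0], row[1]))
        return pairs

    if isinstance(source, str):
        with open(source, encoding="utf-8") as handle:
            return parse(handle)
    return parse(source)


def _group_pairs(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for a, b in pairs:
        out.setdefault(a, set()).add(b)
    return out


def load_corpus(
    disease_terms: PathOrStream,
    mutant_terms: PathOrStream,
    gene_disease: PathOrStream,
    mutant_genes: PathOrStream,
    orthology: PathOrStream,
    ontology: Ontology | None = None,
) -> AssociationDB:
    """Load the annotation corpus from five two-column TSV tables.

    Tables: disease_id/term_id, mutant_id/term_id, gene_id/disease_id,
    mutant_id/mouse_gene_id, mouse_gene_id/human_gene_id.  Duplicate rows are
    deduplicated.  Mutants are attached to every human ortholog of their
    mouse gene (mutants whose gene has no ortholog stay in the corpus but
    appear in no Z_i).  If an ontology is given, terms it cannot resolve are
    dropped with a warning.
    """
    disease_map = _group_pairs(_read_pairs(disease_terms, "disease_terms"))
    mutant_map = _group_pairs(_read_pairs(mutant_terms, "mutant_terms"))
    gene_disease_pairs = set(_read_pairs(gene_disease, "gene_disease"))
    mutant_gene_map = _group_pairs(_read_pairs(mutant_genes, "mutant_genes"))
    ortho_map = _group_pairs(_read_pairs(orthology, "orthology"))

    def resolve(source_id: str, terms: set[str]) -> frozenset[str]:
        if ontology is None:
            return frozenset(terms)
        kept = frozenset(
            t for t in terms if t in ontology and not ontology.terms[t].obsolete
        )
        if len(kept) < len(terms):
            logger.warning(
                "%s: dropped %d unresolvable term(s)",
                source_id,
                len(terms) - len(kept),
            )
        return kept

    db = AssociationDB()
    for did, terms in disease_map.items():
        db.diseases[did] = PhenotypeSource(did, "human_disease", resolve(did, terms))
    for mid, terms in mutant_map.items():
        db.mutants[mid] = PhenotypeSource(mid, "mouse_mutant", resolve(mid, terms))

    for gene, disease in sorted(gene_disease_pairs):
        if disease not in db.diseases:
            logger.warning(
                "gene %s associated with disease %s that has no phenotype terms; "
                "recording with an empty term set",
                gene,
                disease,
            )
            db.diseases[disease] = PhenotypeSource(
                disease, "human_disease", frozenset()
            )
        db.gene_to_diseases.setdefault(gene, set()).add(disease)

    for mid, mouse_genes in mutant_gene_map.items():
        if mid not in db.mutants:
            db.mutants[mid] = PhenotypeSource(mid, "mouse_mutant", frozenset())
        human_genes = set()
        for mg in mouse_genes:
            human_genes |= ortho_map.get(mg, set())
        if len(human_genes) > 1:
            logger.info("mutant %s maps to %d human orthologs", mid, len(human_genes))
        for hg in human_genes:
            db.gene_to_mutants.setdefault(hg, set()).add(mid)
    return db


def build_coannotation_counts(db: AssociationDB) -> AssociationDB:
    """Count, for each term pair, the diseases annotated with both terms.

    Counts use the raw disease->term mapping tables, not closure-expanded
    sets; count(t, t) is the disease frequency of t.  Stored as a symmetric
    sparse matrix on the db (mutated and returned for chaining).
    """
    term_ids = sorted({t for s in db.diseases.values() for t in s.term_ids})
    index = {t: i for i, t in enumerate(term_ids)}
    rows, cols = [], []
    for d, source in enumerate(db.diseases.values()):
        for t in source.term_ids:
            rows.append(d)
            cols.append(index[t])
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(db.diseases), len(term_ids)),
    )
    counts = (incidence.T @ incidence).tocsr()
    db.coannotation = (term_ids, index, counts)
    return db


def mask_association(db: AssociationDB, gene_id: str, disease_id: str) -> AssociationDB:
    """Return a copy of the db with one gene-disease association removed.

    Everything else — the disease's term set, other genes' associations, the
    co-annotation counts — is untouched (counts derive from disease->term
    maps only, so they are shared, not recomputed).
    """
    if disease_id not in db.gene_to_diseases.get(gene_id, set()):
        raise KeyError(
            f"no association between gene {gene_id!r} and disease {disease_id!r}"
        )
    masked = copy.copy(db)
    masked.gene_to_diseases = {g: set(d) for g, d in db.gene_to_diseases.items()}
    masked.gene_to_diseases[gene_id].discard(disease_id)
    return masked
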