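"""Raw per-gene phenotype-relevance scores for a query term set.

The score of gene i against query term set W_q is the mean simGIC similarity
of its associated diseases plus the mean simGIC similarity of the mutants of
its orthologous mouse genes:

    Q_i = sum_{j in Y_i} S(W_q, W_j) / |Y_i| + sum_{k in Z_i} S(W_q, W_k) / |Z_i|

Each block is a mean of values in [0, 1], so 0 <= Q_i <= 2; a gene with no
sources in a block gets 0 from that block.  Only genes present in the PPI
network are scored.

:class:`PhenotypeScorer` precomputes IC-weighted closure incidence matrices
for every phenotype source and sparse gene-source incidence, so that scoring
one query set against all network genes is a pair of sparse mat-vecs.  This
matters because a prioritization run scores the query plus up to 1000
simulated term sets against the same corpus.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

from .annotations import AssociationDB
from .network import PPINetwork
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = ["PhenotypeScorer", "raw_gene_scores"]

SPECIES_MODES = ("both", "human_only", "mouse_only")


class PhenotypeScorer:
    """Scores any query term set against every gene in the network.

    The similarity of the query closure C_q to a source closure C_j is
    computed from inner products with the IC vector w:

        inter_j = sum_{t in C_j ∩ C_q} w_t = B_j . (c_q * w)
        S_j     = inter_j / (B_j . w + c_q . w - inter_j)

    where B is the binary source-by-term closure incidence matrix and c_q
    the binary closure indicator of the query.  Terms with undefined IC are
    simply absent from the term index.
    """

    def __init__(
        self,
        db: AssociationDB,
        network: PPINetwork,
        ontology: Ontology,
        species_mode: str = "both",
    ):
        if not ontology.has_ic:
            raise ValueError(
                "ontology has no information content; run compute_ic first"
            )
        if species_mode not in SPECIES_MODES:
            raise ValueError(f"species_mode must be one of {SPECIES_MODES}")
        self.db = db
        self.network = network
        self.ontology = ontology
        self.species_mode = species_mode

        self._term_ids = sorted(ontology.ic)
        self._term_index = {t: i for i, t in enumerate(self._term_ids)}
        self._ic = np.array([ontology.ic[t] for t in self._term_ids])

        self._disease_ids = sorted(db.diseases)
        self._mutant_ids = sorted(db.mutants)
        self._b_disease, self._icsum_disease = self._closure_matrix(
            [db.diseases[d].term_ids for d in self._disease_ids]
        )
        self._b_mutant, self._icsum_mutant = self._closure_matrix(
            [db.mutants[m].term_ids for m in self._mutant_ids]
        )

        skipped = [g for g in db.genes() if g not in network]
        if skipped:
            logger.info(
                "%d annotated gene(s) absent from the PPI network are not scored",
                len(skipped),
            )
        self._gy = self._incidence(
            db.gene_to_diseases, {d: i for i, d in enumerate(self._disease_ids)}
        )
        self._gz = self._incidence(
            db.gene_to_mutants, {m: i for i, m in enumerate(self._mutant_ids)}
        )

    def _closure_matrix(
        self, term_sets: list[frozenset[str]]
    ) -> tuple[sparse.csr_matrix, np.ndarray]:
        rows, cols = [], []
        for i, terms in enumerate(term_sets):
            for t in self.ontology.closure_of_set(terms):
                j = self._term_index.get(t)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
        mat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(term_sets), len(self._term_ids)),
        )
        return mat, mat @ self._ic

    def _incidence(
        self, gene_to_sources: dict[str, set[str]], source_index: dict[str, int]
    ) -> sparse.csr_matrix:
        """Gene-by-source matrix with rows scaled by 1/|sources of gene|."""
        rows, cols, vals = [], [], []
        for gene, sources in gene_to_sources.items():
            gi = self.network.index.get(gene)
            if gi is None or not sources:
                continue
            weight = 1.0 / len(sources)
            for s in sources:
                rows.append(gi)
                cols.append(source_index[s])
                vals.append(weight)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.network.n, len(source_index))
        )

    def source_similarities(
        self, w_q: frozenset[str] | set[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """simGIC of the query set against every disease and every mutant."""
        cq = np.zeros(len(self._term_ids))
        for t in self.ontology.closure_of_set(w_q):
            j = self._term_index.get(t)
            if j is not None:
                cq[j] = 1.0
        icsum_q = float(cq @ self._ic)

        def sims(b: sparse.csr_matrix, icsum: np.ndarray) -> np.ndarray:
            inter = b @ (cq * self._ic)
            denom = icsum + icsum_q - inter
            return np.divide(
                inter, denom, out=np.zeros_like(inter), where=denom > 0.0
            )

        return (
            sims(self._b_disease, self._icsum_disease),
            sims(self._b_mutant, self._icsum_mutant),
        )

    def gene_scores(self, w_q: frozenset[str] | set[str]) -> np.ndarray:
        """Raw scores Q_i for every network gene, in network node order."""
        sim_d, sim_m = self.source_similarities(w_q)
        scores = np.zeros(self.network.n)
        if self.species_mode in ("both", "human_only"):
            scores += self._gy @ sim_d
        if self.species_mode in ("both", "mouse_only"):
            scores += self._gz @ sim_m
        return scores


def raw_gene_scores(
    w_q: frozenset[str] | set[str],
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    species_mode: str = "both",
) -> dict[str, float]:
    """Raw score Q_i per network gene as a mapping (convenience wrapper)."""
    scorer = PhenotypeScorer(db, network, ontology, species_mode)
    scores = scorer.gene_scores(w_q)
    return dict(zip(network.gene_ids, scores.tolist()))
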