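"""Full prioritization pipeline: score, propagate, rank, simulate, p-values.

For a query disease (or explicit term set) the pipeline computes raw gene
scores, propagates them over the PPI network, and ranks genes.  In
simulation mode the identical pipeline is then rerun for u simulated
phenotype-term sets of the same size — with all other data unchanged — and
each gene receives an empirical p-value: the proportion of simulated runs in
which the gene ranks strictly better than in the query run, floored at 1/u.
Because data availability affects the query run and every null run equally,
the p-values are insensitive to how well-studied each gene is; that is the
entire point of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import numpy as np

from .annotations import AssociationDB, build_coannotation_counts, mask_association
from .network import PPINetwork, column_normalize, rank_scores, rwr_propagate
from .ontology import Ontology
from .scoring import PhenotypeScorer
from .simulation import SimulationConfig, simulate_term_set

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PrioritizationResult",
    "resolve_query",
    "empirical_pvalues",
    "phenorank",
    "write_results",
]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one prioritization run.

    Defaults: restart probability r = 0.1, 20 RWR iterations, u = 1000
    simulated term sets.  ``mode="no_simulation"`` skips the null entirely
    and reports propagated scores/ranks only.  ``species_mode`` restricts
    the raw score to the human-disease or mouse-mutant block for ablation.
    """

    r: float = 0.1
    n_iter: int = 20
    n_sets: int = 1000
    rng_seed: int = 0
    mode: str = "simulation"  # "simulation" | "no_simulation"
    species_mode: str = "both"  # "both" | "human_only" | "mouse_only"
    masked_associations: tuple[tuple[str, str], ...] = ()
    max_seed_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("simulation", "no_simulation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PrioritizationResult:
    """Per-gene outputs of a run, aligned with ``gene_ids``."""

    gene_ids: list[str]
    raw_scores: np.ndarray
    propagated_scores: np.ndarray
    ranks: np.ndarray
    p_values: np.ndarray | None  # None in no_simulation mode
    query_id: str | None
    query_terms: frozenset[str]
    config: RunConfig = field(default_factory=RunConfig)

    def as_dict(self, gene_id: str) -> dict[str, float]:
        i = self.gene_ids.index(gene_id)
        out = {
            "raw_score": float(self.raw_scores[i]),
            "propagated_score": float(self.propagated_scores[i]),
            "rank": float(self.ranks[i]),
        }
        if self.p_values is not None:
            out["p_value"] = float(self.p_values[i])
        return out


def resolve_query(
    query: Union[str, Iterable[str]], db: AssociationDB, ontology: Ontology | None = None
) -> frozenset[str]:
    """Resolve a query to its term set W_q.

    A string is a catalogued disease id (its mapped term set is used
    verbatim); an iterable is an explicit term list, filtered to terms the
    ontology resolves (dropped terms are warned about).
    """
    if isinstance(query, str):
        source = db.diseases.get(query)
        if source is None:
            raise KeyError(f"unknown disease id {query!r}")
        if not source.term_ids:
            raise ValueError(f"disease {query!r} has no phenotype terms")
        return source.term_ids
    terms = list(dict.fromkeys(query))
    if ontology is not None:
        kept = [t for t in terms if t in ontology and not ontology.terms[t].obsolete]
        if len(kept) < len(terms):
            logger.warning(
                "dropped %d unresolvable query term(s)", len(terms) - len(kept)
            )
        terms = kept
    if not terms:
        raise ValueError("query resolves to zero phenotype terms")
    return frozenset(terms)


def empirical_pvalues(
    query_ranks: np.ndarray, sim_ranks: Sequence[np.ndarray] | np.ndarray, u: int
) -> np.ndarray:
    """p(g) = max(b(g)/u, 1/u): b = simulated runs ranking g strictly better.

    "Better" means a strictly smaller rank; exact rank ties between the
    query run and a simulated run do not count against the gene, which makes
    the p-value conservative.
    """
    sim_ranks = np.asarray(sim_ranks, dtype=float)
    if sim_ranks.ndim != 2 or sim_ranks.shape[0] != u:
        raise ValueError(
            f"expected {u} simulated rank vectors, got shape {sim_ranks.shape}"
        )
    if sim_ranks.shape[1] != np.asarray(query_ranks).shape[0]:
        raise ValueError("simulated and query rank vectors cover different genes")
    b = (sim_ranks < np.asarray(query_ranks, dtype=float)[None, :]).sum(axis=0)
    return np.maximum(b, 1) / float(u)


def _pipeline(
    scorer: PhenotypeScorer, a_norm, w: frozenset[str], r: float, n_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """score -> normalize -> propagate -> rank, shared by query and null runs."""
    raw = scorer.gene_scores(w)
    total = raw.sum()
    q0 = raw / total if total > 0 else raw
    propagated = rwr_propagate(a_norm, q0, r, n_iter)
    return raw, propagated, rank_scores(propagated)


def phenorank(
    query: Union[str, Iterable[str]],
    config: RunConfig,
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
) -> PrioritizationResult:
    """Run the full prioritization for one query.

    The same data (db, network, ontology, masking) back the query run and
    every simulated run; only the term set changes between runs.
    """
    masked_db = db
    for gene_id, disease_id in config.masked_associations:
        masked_db = mask_association(masked_db, gene_id, disease_id)

    query_id = query if isinstance(query, str) else None
    w_q = resolve_query(query, masked_db, ontology)

    scorer = PhenotypeScorer(masked_db, network, ontology, config.species_mode)
    a_norm = column_normalize(network)
    raw, propagated, ranks = _pipeline(scorer, a_norm, w_q, config.r, config.n_iter)
    degenerate = raw.sum() == 0
    if degenerate:
        logger.warning(
            "query %s yields an all-zero score vector: every gene ties and, in "
            "simulation mode, every p-value is 1",
            query_id or sorted(w_q),
        )

    p_values = None
    if config.mode == "simulation" and degenerate:
        # no evidence for any gene: the null is not run, nothing is implicated
        p_values = np.ones(network.n)
    elif config.mode == "simulation":
        if masked_db.coannotation is None:
            build_coannotation_counts(masked_db)
        sim_cfg = SimulationConfig(
            n_sets=config.n_sets,
            max_seed_attempts=config.max_seed_attempts,
            rng_seed=config.rng_seed,
        )
        sim_ranks = np.empty((config.n_sets, network.n))
        for k in range(sim_cfg.n_sets):
            rng = np.random.default_rng((sim_cfg.rng_seed, k))
            w_sim = simulate_term_set(
                len(w_q), masked_db, rng, sim_cfg.max_seed_attempts
            )
            _, _, sim_ranks[k] = _pipeline(
                scorer, a_norm, w_sim, config.r, config.n_iter
            )
        p_values = empirical_pvalues(ranks, sim_ranks, config.n_sets)

    return PrioritizationResult(
        gene_ids=list(network.gene_ids),
        raw_scores=raw,
        propagated_scores=propagated,
        ranks=ranks,
        p_values=p_values,
        query_id=query_id,
        query_terms=w_q,
        config=config,
    )


def write_results(result: PrioritizationResult, stream: IO[str]) -> None:
    """Write a result as TSV: metadata comments, header, one row per gene.

    Rows are sorted by ascending p-value (simulation mode), then rank, then
    gene id; floats are printed at 6 significant digits.  Output is
    byte-deterministic given identical inputs and seed.
    """
    cfg = result.config
    stream.write("# phenorank results\n")
    stream.write(f"# query_id: {result.query_id or '-'}\n")
    stream.write(f"# query_terms: {','.join(sorted(result.query_terms))}\n")
    stream.write(
        f"# r: {cfg.r}\n# n_iter: {cfg.n_iter}\n# mode: {cfg.mode}\n"
        f"# species_mode: {cfg.species_mode}\n"
    )
    if result.p_values is not None:
        stream.write(f"# n_sets: {cfg.n_sets}\n# rng_seed: {cfg.rng_seed}\n")

    with_p = result.p_values is not None
    header = ["gene_id", "raw_score", "propagated_score", "rank"]
    if with_p:
        header.append("p_value")
    stream.write("\t".join(header) + "\n")

    order = sorted(
        range(len(result.gene_ids)),
        key=lambda i: (
            float(result.p_values[i]) if with_p else 0.0,
            float(result.ranks[i]),
            result.gene_ids[i],
        ),
    )
    for i in order:
        row = [
            result.gene_ids[i],
            f"{result.raw_scores[i]:.6g}",
            f"{result.propagated_scores[i]:.6g}",
            f"{result.ranks[i]:.6g}",
        ]
        if with_p:
            row.append(f"{result.p_values[i]:.6g}")
        stream.write("\t".join(row) + "\n")
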