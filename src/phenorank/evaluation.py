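"""Evaluation harness: leave-one-out CV, ROC/AUC, bias features, correlations.

Leave-one-out cross-validation masks one known disease-gene association,
reruns the prioritization with the disease as query, and measures how well
the masked gene is recovered relative to all other eligible genes (genes
also associated with the trial disease are excluded).  Pooling the per-trial
scores of masked (positive) and eligible-other (negative) genes yields a ROC
curve and its AUC.

The bias machinery quantifies how strongly a method's gene scores track data
availability: the per-gene feature table covers network degree, the number
of phenotype sources, annotation-set sizes and ontology depths; correlations
are Spearman's rho.  p-value based scores are flipped to -log10(p) so that
"higher = more implicated" holds for every method variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .annotations import AssociationDB, build_coannotation_counts
from .network import PPINetwork
from .ontology import Ontology
from .prioritize import PrioritizationResult, RunConfig, phenorank

logger = logging.getLogger(__name__)

__all__ = [
    "CVTrial",
    "loo_cross_validation",
    "roc_auc",
    "bias_features",
    "bias_correlations",
    "bias_correlation_study",
    "stratified_cv",
    "tune_restart_probability",
]

FEATURE_COLUMNS = [
    "degree",
    "n_phenotype_sources",
    "median_n_terms",
    "median_abs_term_diff",
    "median_max_depth",
]


@dataclass(frozen=True)
class CVTrial:
    """One cross-validation trial: a masked association and its outcome."""

    disease_id: str
    gene_id: str
    masked_gene_rank: float  # rank within eligible genes, 1 = best
    n_eligible: int


def method_scores(result: PrioritizationResult) -> np.ndarray:
    """Higher-is-better gene scores for evaluation.

    Simulation mode: -log10(p).  NoSimulation mode: the propagated score.
    """
    if result.p_values is not None:
        return -np.log10(result.p_values)
    return result.propagated_scores


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUC = normalized Mann-Whitney U; score ties contribute 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def loo_cross_validation(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    config: RunConfig,
    trials: Iterable[tuple[str, str]],
) -> tuple[list[CVTrial], float]:
    """Run LOO CV over (disease_id, gene_id) trials; returns trials + pooled AUC.

    Eligible genes per trial are all scored network genes except those also
    associated with the trial disease; the masked gene itself is always
    eligible.  Every trial association must exist and its gene must be in
    the network.
    """
    if config.mode == "simulation" and db.coannotation is None:
        build_coannotation_counts(db)
    pooled_labels: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    outcomes: list[CVTrial] = []
    for disease_id, gene_id in trials:
        if disease_id not in db.gene_to_diseases.get(gene_id, set()):
            raise KeyError(
                f"trial association ({gene_id!r}, {disease_id!r}) not in corpus"
            )
        if gene_id not in network:
            raise KeyError(f"trial gene {gene_id!r} not in the PPI network")
        cfg = replace(
            config,
            masked_associations=config.masked_associations
            + ((gene_id, disease_id),),
        )
        result = phenorank(disease_id, cfg, db, network, ontology)
        scores = method_scores(result)

        coassociated = {
            g
            for g, diseases in db.gene_to_diseases.items()
            if disease_id in diseases and g != gene_id
        }
        eligible = np.array(
            [g not in coassociated for g in result.gene_ids], dtype=bool
        )
        gi = result.gene_ids.index(gene_id)
        elig_scores = scores[eligible]
        # rank of the masked gene among eligible genes (ties -> average)
        better = np.sum(elig_scores > scores[gi])
        tied = np.sum(elig_scores == scores[gi])
        masked_rank = better + (tied + 1) / 2.0
        outcomes.append(
            CVTrial(
                disease_id=disease_id,
                gene_id=gene_id,
                masked_gene_rank=float(masked_rank),
                n_eligible=int(eligible.sum()),
            )
        )
        labels = np.array(
            [1 if g == gene_id else 0 for g, e in zip(result.gene_ids, eligible) if e]
        )
        pooled_labels.append(labels)
        pooled_scores.append(elig_scores)
    auc = roc_auc(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
    return outcomes, auc


def bias_features(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    w_q: Iterable[str],
) -> pd.DataFrame:
    """Per-gene data-availability features, indexed by network gene id.

    Columns: (i) network degree; (ii) number of phenotype sources
    |Y_i| + |Z_i|; (iii) median term-set size over the gene's sources;
    (iv) median absolute difference between |W_q| and source term-set sizes;
    (v) median over sources of the maximum ontology depth of their terms.
    Features (ii)-(v) are NaN for genes with no phenotype sources.
    """
    w_q = set(w_q)
    degrees = network.degrees()
    rows = []
    for gi, gene in enumerate(network.gene_ids):
        sources = [
            db.diseases[d] for d in sorted(db.gene_to_diseases.get(gene, set()))
        ] + [db.mutants[m] for m in sorted(db.gene_to_mutants.get(gene, set()))]
        row: dict[str, float] = {"degree": float(degrees[gi])}
        if not sources:
            row.update({c: np.nan for c in FEATURE_COLUMNS[1:]})
        else:
            sizes = [len(s.term_ids) for s in sources]
            depths = [
                max((ontology.max_depth(t) for t in s.term_ids), default=np.nan)
                for s in sources
            ]
            row["n_phenotype_sources"] = float(len(sources))
            row["median_n_terms"] = float(np.median(sizes))
            row["median_abs_term_diff"] = float(
                np.median([abs(len(w_q) - n) for n in sizes])
            )
            row["median_max_depth"] = float(np.nanmedian(depths))
        rows.append(row)
    return pd.DataFrame(rows, index=network.gene_ids, columns=FEATURE_COLUMNS)


def bias_correlations(
    gene_scores: Sequence[float] | np.ndarray,
    feature_table: pd.DataFrame,
    scores_are_pvalues: bool = False,
) -> dict[str, float]:
    """Spearman rho between gene scores and each data-availability feature.

    Pairwise-complete over genes with a defined feature value.  p-value
    scores are flipped to -log10(p) first.  Degenerate constant vectors
    yield NaN with a warning.
    """
    scores = np.asarray(gene_scores, dtype=float)
    if scores_are_pvalues:
        scores = -np.log10(scores)
    out: dict[str, float] = {}
    for feature in feature_table.columns:
        values = feature_table[feature].to_numpy(dtype=float)
        mask = np.isfinite(values) & np.isfinite(scores)
        if mask.sum() < 3:
            logger.warning("feature %s: fewer than 3 defined values", feature)
            out[feature] = float("nan")
            continue
        if np.ptp(values[mask]) == 0 or np.ptp(scores[mask]) == 0:
            logger.warning("feature %s: constant vector, rho undefined", feature)
            out[feature] = float("nan")
            continue
        rho, _ = spearmanr(scores[mask], values[mask])
        out[feature] = float(rho)
    return out


def bias_correlation_study(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    queries: Sequence[str],
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Score-vs-feature correlations over a panel of query diseases.

    Each query is run once in simulation mode; the propagated scores of the
    same run serve as the NoSimulation variant (identical query-side
    pipeline).  Returns one query-by-feature rho table per method variant,
    keyed "simulation" and "no_simulation"; averaging rows gives the
    method's overall bias profile.
    """
    rho_sim, rho_nosim = [], []
    for query in queries:
        result = phenorank(query, config, db, network, ontology)
        table = bias_features(db, network, ontology, result.query_terms)
        rho_sim.append(
            bias_correlations(result.p_values, table, scores_are_pvalues=True)
        )
        rho_nosim.append(bias_correlations(result.propagated_scores, table))
    return {
        "simulation": pd.DataFrame(rho_sim, index=list(queries)),
        "no_simulation": pd.DataFrame(rho_nosim, index=list(queries)),
    }


def stratified_cv(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    config: RunConfig,
    trials: Sequence[tuple[str, str]],
    strata_key: str = "degree",
    n_strata: int = 5,
) -> pd.DataFrame:
    """LOO CV per quantile stratum of a per-trial data-availability key.

    ``strata_key`` is "degree" (network degree of the trial gene) or
    "n_phenotype_sources" (|Y_i| + |Z_i| of the trial gene).  Trials are
    sorted by key and split into ``n_strata`` near-equal strata; empty
    strata are flagged and skipped.
    """
    if len(trials) < n_strata:
        raise ValueError("need at least one trial per stratum")
    if strata_key == "degree":
        keys = [network.degree(g) for _, g in trials]
    elif strata_key == "n_phenotype_sources":
        keys = [
            len(db.gene_to_diseases.get(g, set()))
            + len(db.gene_to_mutants.get(g, set()))
            for _, g in trials
        ]
    else:
        raise ValueError(f"unknown strata_key {strata_key!r}")

    order = np.argsort(np.asarray(keys), kind="stable")
    strata = np.array_split(order, n_strata)
    records = []
    for si, stratum in enumerate(strata):
        if stratum.size == 0:
            logger.warning("stratum %d is empty; skipped", si)
            continue
        sub = [trials[i] for i in stratum]
        _, auc = loo_cross_validation(db, network, ontology, config, sub)
        records.append(
            {
                "stratum": si,
                "n_trials": len(sub),
                "key_min": float(min(keys[i] for i in stratum)),
                "key_max": float(max(keys[i] for i in stratum)),
                "auc": auc,
            }
        )
    return pd.DataFrame.from_records(records)


def tune_restart_probability(
    db: AssociationDB,
    network: PPINetwork,
    ontology: Ontology,
    config: RunConfig,
    r_grid: Sequence[float],
    tuning_trials: Sequence[tuple[str, str]],
    eval_trials: Sequence[tuple[str, str]] = (),
) -> tuple[float, pd.DataFrame]:
    """Grid-search the restart probability r on a held-out association set.

    ``tuning_trials`` must be disjoint from ``eval_trials`` (enforced), so
    parameter selection cannot leak into performance evaluation.  Returns
    the AUC-maximizing r and the full grid as a DataFrame.
    """
    overlap = set(tuning_trials) & set(eval_trials)
    if overlap:
        raise ValueError(
            f"tuning and evaluation trials must be disjoint; shared: {sorted(overlap)}"
        )
    records = []
    for r in r_grid:
        _, auc = loo_cross_validation(
            db, network, ontology, replace(config, r=float(r)), tuning_trials
        )
        records.append({"r": float(r), "auc": auc})
    grid = pd.DataFrame.from_records(records)
    best_r = float(grid.loc[grid["auc"].idxmax(), "r"])
    return best_r, grid
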