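"""Simulated phenotype-term sets: the empirical null of the method.

A simulated set of a given size is built by sampling a seed term uniformly
from the terms mapped to at least one disease, ranking all terms by how
often they are co-mapped to the same disease as the seed (ties broken
uniformly at random; the seed participates with its own disease frequency),
and keeping the top ``size`` terms.  Seeds with fewer than ``size``
positively co-mapped terms are rejected and redrawn.  The construction makes
simulated sets resemble real disease annotations — terms that co-occur on
diseases co-occur in the null — while being unrelated to any query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AssociationDB

__all__ = ["SimulationConfig", "simulate_term_set", "simulate_null_batch"]


@dataclass(frozen=True)
class SimulationConfig:
    """Null-simulation parameters: u simulated sets, bounded seed retries."""

    n_sets: int = 1000
    max_seed_attempts: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.max_seed_attempts < 1:
            raise ValueError("max_seed_attempts must be >= 1")


def simulate_term_set(
    size: int,
    db: AssociationDB,
    rng: np.random.Generator,
    max_seed_attempts: int = 1000,
) -> frozenset[str]:
    """Draw one simulated term set of exactly ``size`` terms.

    Raises ``ValueError`` if no admissible seed is found within
    ``max_seed_attempts`` draws, reporting the largest admissible size.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if db.coannotation is None:
        raise ValueError("co-annotation counts not built; run build_coannotation_counts")
    term_ids, _, counts = db.coannotation
    if not term_ids:
        raise ValueError("no terms are mapped to any disease")

    for _ in range(max_seed_attempts):
        seed_idx = int(rng.integers(len(term_ids)))
        row = counts[seed_idx].toarray().ravel()
        positive = np.flatnonzero(row > 0)
        if positive.size < size:
            continue  # seed inadmissible: redraw
        # Rank by co-count descending, ties in uniform random order.
        tiebreak = rng.random(positive.size)
        order = np.lexsort((tiebreak, -row[positive]))
        top = positive[order[:size]]
        return frozenset(term_ids[i] for i in top)

    max_admissible = int(np.max((counts > 0).sum(axis=1)))
    raise ValueError(
        f"no seed term admits a simulated set of size {size} after "
        f"{max_seed_attempts} attempts; largest admissible size is {max_admissible}"
    )


def simulate_null_batch(
    size: int, config: SimulationConfig, db: AssociationDB
) -> list[frozenset[str]]:
    """Draw ``config.n_sets`` independent simulated sets of the given size.

    Each set uses its own RNG stream derived from ``(rng_seed, set index)``,
    so results are reproducible and independent of evaluation order.
    """
    return [
        simulate_term_set(
            size,
            db,
            np.random.default_rng((config.rng_seed, k)),
            config.max_seed_attempts,
        )
        for k in range(config.n_sets)
    ]
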