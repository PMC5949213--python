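"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from primitive data structures (parent dicts, dense
matrices, raw score lists) and deliberately shares no code with the package
internals it is used to verify.
"""

from __future__ import annotations

import math

import numpy as np


def bf_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive transitive closure by graph search."""
    out = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in parents[node]:
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def bf_closure_of_set(parents: dict[str, set[str]], terms) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out |= bf_ancestors(parents, t)
    return out


def bf_ic(parents: dict[str, set[str]], corpus: list[tuple[str, set[str]]]) -> dict:
    """IC by explicit closure counting over the corpus."""
    counts: dict[str, int] = {}
    for _, terms in corpus:
        for t in bf_closure_of_set(parents, terms):
            counts[t] = counts.get(t, 0) + 1
    n = len(corpus)
    return {t: -math.log(c / n) for t, c in counts.items()}


def bf_sim_gic(
    w_i, w_j, parents: dict[str, set[str]], ic: dict[str, float]
) -> float:
    ci = bf_closure_of_set(parents, w_i)
    cj = bf_closure_of_set(parents, w_j)
    num = sum(ic.get(t, 0.0) for t in ci & cj)
    den = sum(ic.get(t, 0.0) for t in ci | cj)
    return num / den if den > 0 else 0.0


def bf_max_depth(parents: dict[str, set[str]], term: str) -> int:
    """Longest path to a root by exhaustive recursion."""
    if not parents[term]:
        return 0
    return 1 + max(bf_max_depth(parents, p) for p in parents[term])


def rwr_closed_form(a_dense: np.ndarray, q0: np.ndarray, r: float) -> np.ndarray:
    """Steady state r (I - (1-r) A)^-1 Q^0 by direct linear solve."""
    n = a_dense.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * a_dense, q0)


def bf_rank_desc(scores) -> np.ndarray:
    """Descending ranks with average ties, via sorting and tie groups."""
    scores = np.asarray(scores, dtype=float)
    ranks = np.empty(len(scores))
    for i, s in enumerate(scores):
        higher = np.sum(scores > s)
        tied = np.sum(scores == s)
        ranks[i] = higher + (tied + 1) / 2.0
    return ranks


def bf_auc(labels, scores) -> float:
    """AUC by exhaustive positive/negative pair comparison (ties = 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def parents_of(ontology) -> dict[str, set[str]]:
    """Extract the raw parent structure (data only, no package logic)."""
    return {
        t.id: set(t.parent_ids)
        for t in ontology.terms.values()
        if not t.obsolete
    }
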