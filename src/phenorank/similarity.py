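"""simGIC phenotypic similarity between sets of phenotype-ontology terms.

simGIC is the Jaccard coefficient weighted by per-term information content,
computed after both term sets are expanded to their ancestor closures (true
path rule):

    S(W_i, W_j) = sum_{x in W_i ∩ W_j} IC(x) / sum_{y in W_i ∪ W_j} IC(y)

Terms with undefined IC (never annotated in the corpus) contribute nothing;
a zero denominator — including two empty sets — yields similarity 0, so
annotation-free sources never appear phenotypically similar to anything.
"""

from __future__ import annotations

from typing import IO, Iterable, Mapping

from .ontology import Ontology

__all__ = ["sim_gic", "similarity_matrix", "write_similarity_matrix"]


def sim_gic(w_i: Iterable[str], w_j: Iterable[str], ontology: Ontology) -> float:
    """IC-weighted Jaccard similarity of two term sets, in [0, 1]."""
    if not ontology.has_ic:
        raise ValueError("ontology has no information content; run compute_ic first")
    ci = ontology.closure_of_set(w_i)
    cj = ontology.closure_of_set(w_j)
    ic = ontology.ic
    num = sum(ic.get(t, 0.0) for t in ci & cj)
    den = sum(ic.get(t, 0.0) for t in ci | cj)
    return num / den if den > 0.0 else 0.0


def similarity_matrix(
    sources: Mapping[str, Iterable[str]], ontology: Ontology
) -> tuple[list[str], list[list[float]]]:
    """All-against-all simGIC over named term sets (e.g. disease x disease)."""
    ids = list(sources)
    closures = {sid: ontology.closure_of_set(sources[sid]) for sid in ids}
    ic = ontology.ic
    sums = {sid: sum(ic.get(t, 0.0) for t in clo) for sid, clo in closures.items()}
    matrix = []
    for a in ids:
        row = []
        for b in ids:
            num = sum(ic.get(t, 0.0) for t in closures[a] & closures[b])
            den = sums[a] + sums[b] - num
            row.append(num / den if den > 0.0 else 0.0)
        matrix.append(row)
    return ids, matrix


def write_similarity_matrix(
    sources: Mapping[str, Iterable[str]], ontology: Ontology, stream: IO[str]
) -> None:
    """Write the all-against-all similarity matrix as TSV with a header row."""
    ids, matrix = similarity_matrix(sources, ontology)
    stream.write("\t".join(["id"] + ids) + "\n")
    for sid, row in zip(ids, matrix):
        stream.write("\t".join([sid] + [f"{v:.6g}" for v in row]) + "\n")
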