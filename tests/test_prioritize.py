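import io

import numpy as np
import pandas as pd
import pytest

from phenorank.annotations import build_coannotation_counts, load_corpus
from phenorank.network import PPINetwork
from phenorank.ontology import compute_ic, parse_obo
from phenorank.prioritize import (
    RunConfig,
    empirical_pvalues,
    phenorank,
    resolve_query,
    write_results,
)


def _tsv(rows):
    return io.StringIO("".join(f"{a}\t{b}\n" for a, b in rows))


@pytest.fixture
def mini_world():
    """10 genes on a path; g3's disease dQ is annotated exactly like the query."""
    stanzas = ["[Term]\nid: root\nname: root\n"]
    for i in range(12):
        stanzas.append(f"[Term]\nid: t{i}\nname: t{i}\nis_a: root\n")
    onto = parse_obo("\n".join(stanzas))
    genes = [f"g{i}" for i in range(10)]
    disease_rows = [("dQ", "t0"), ("dQ", "t1"), ("dQ", "t2")]
    for i in range(8):  # background diseases on other terms
        disease_rows += [(f"d{i}", f"t{(i % 8) + 4}"), (f"d{i}", f"t{((i + 1) % 8) + 4}")]
    db = load_corpus(
        disease_terms=_tsv(disease_rows),
        mutant_terms=_tsv([("m0", "t5")]),
        gene_disease=_tsv(
            [("g3", "dQ")] + [(f"g{i}", f"d{i}") for i in range(8) if i != 3]
        ),
        mutant_genes=_tsv([("m0", "mg0")]),
        orthology=_tsv([("mg0", "g9")]),
    )
    corpus = [(s.id, s.term_ids) for s in db.diseases.values()] + [
        (s.id, s.term_ids) for s in db.mutants.values()
    ]
    compute_ic(onto, corpus)
    build_coannotation_counts(db)
    net = PPINetwork(genes, [(genes[i], genes[i + 1]) for i in range(9)])
    return onto, db, net


class TestResolveQuery:
    def test_catalogued_disease_verbatim(self, mini_world):
        _, db, _ = mini_world
        assert resolve_query("dQ", db) == {"t0", "t1", "t2"}

    def test_unknown_disease_errors(self, mini_world):
        _, db, _ = mini_world
        with pytest.raises(KeyError):
            resolve_query("nope", db)

    def test_bogus_term_dropped_with_warning(self, mini_world, caplog):
        onto, db, _ = mini_world
        with caplog.at_level("WARNING"):
            terms = resolve_query(["t0", "t1", "t2", "t3", "BOGUS:1"], db, onto)
        assert terms == {"t0", "t1", "t2", "t3"}
        assert "unresolvable" in caplog.text

    def test_empty_list_errors(self, mini_world):
        _, db, _ = mini_world
        with pytest.raises(ValueError):
            resolve_query([], db)


class TestEmpiricalPvalues:
    def test_proportion(self):
        query = np.array([10.0])
        sims = np.concatenate([np.full((50, 1), 5.0), np.full((950, 1), 15.0)])
        assert empirical_pvalues(query, sims, 1000)[0] == pytest.approx(0.05)

    def test_floor_applied_when_never_beaten(self):
        query = np.array([1.0])
        sims = np.full((1000, 1), 2.0)
        assert empirical_pvalues(query, sims, 1000)[0] == pytest.approx(0.001)

    def test_exact_ties_do_not_count_as_better(self):
        query = np.array([3.0])
        sims = np.full((100, 1), 3.0)
        assert empirical_pvalues(query, sims, 100)[0] == pytest.approx(0.01)

    def test_u_mismatch_errors(self):
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([1.0]), np.ones((5, 1)), 6)


class TestPhenorank:
    def test_identically_annotated_gene_ranks_first(self, mini_world):
        onto, db, net = mini_world
        cfg = RunConfig(n_sets=50, rng_seed=4)
        result = phenorank("dQ", cfg, db, net, onto)
        assert result.ranks[result.gene_ids.index("g3")] == 1.0
        assert result.p_values is not None
        assert np.all(result.p_values >= 1.0 / cfg.n_sets)
        assert np.all(result.p_values <= 1.0)

    def test_no_simulation_mode_has_no_pvalues(self, mini_world):
        onto, db, net = mini_world
        res = phenorank("dQ", RunConfig(mode="no_simulation"), db, net, onto)
        assert res.p_values is None
        # and it is seed-independent: same output for different seeds
        res2 = phenorank(
            "dQ", RunConfig(mode="no_simulation", rng_seed=999), db, net, onto
        )
        assert np.array_equal(res.propagated_scores, res2.propagated_scores)

    def test_no_simulation_matches_query_side_of_simulation_run(self, mini_world):
        onto, db, net = mini_world
        sim = phenorank("dQ", RunConfig(n_sets=20, rng_seed=1), db, net, onto)
        nosim = phenorank("dQ", RunConfig(mode="no_simulation"), db, net, onto)
        assert np.array_equal(sim.ranks, nosim.ranks)
        assert np.array_equal(sim.propagated_scores, nosim.propagated_scores)

    def test_masking_excludes_association_from_raw_score(self, mini_world):
        onto, db, net = mini_world
        cfg = RunConfig(mode="no_simulation", masked_associations=(("g3", "dQ"),))
        masked = phenorank("dQ", cfg, db, net, onto)
        full = phenorank("dQ", RunConfig(mode="no_simulation"), db, net, onto)
        gi = masked.gene_ids.index("g3")
        assert masked.raw_scores[gi] == 0.0  # dQ was g3's only source
        assert full.raw_scores[gi] == pytest.approx(1.0)

    def test_all_zero_query_yields_unit_pvalues_and_warning(self, mini_world, caplog):
        onto, db, net = mini_world
        # t3 annotates no disease or mutant -> no IC -> zero everywhere
        with caplog.at_level("WARNING"):
            res = phenorank(["t3"], RunConfig(n_sets=10), db, net, onto)
        assert np.all(res.raw_scores == 0.0)
        assert np.all(res.p_values == 1.0)
        assert "all-zero" in caplog.text

    def test_deterministic_under_seed(self, mini_world):
        onto, db, net = mini_world
        cfg = RunConfig(n_sets=30, rng_seed=77)
        r1 = phenorank("dQ", cfg, db, net, onto)
        r2 = phenorank("dQ", cfg, db, net, onto)
        assert np.array_equal(r1.p_values, r2.p_values)


class TestWriteResults:
    def test_rows_header_and_comments(self, mini_world):
        onto, db, net = mini_world
        res = phenorank("dQ", RunConfig(n_sets=20, rng_seed=2), db, net, onto)
        buf = io.StringIO()
        write_results(res, buf)
        lines = buf.getvalue().splitlines()
        comments = [l for l in lines if l.startswith("#")]
        data = [l for l in lines if not l.startswith("#")]
        assert data[0].split("\t") == [
            "gene_id", "raw_score", "propagated_score", "rank", "p_value",
        ]
        assert len(data) == 1 + net.n
        assert any("query_id: dQ" in c for c in comments)

    def test_roundtrip_to_printed_precision(self, mini_world):
        onto, db, net = mini_world
        res = phenorank("dQ", RunConfig(n_sets=20, rng_seed=2), db, net, onto)
        buf = io.StringIO()
        write_results(res, buf)
        buf.seek(0)
        df = pd.read_csv(buf, sep="\t", comment="#").set_index("gene_id")
        for gene in res.gene_ids:
            row = df.loc[gene]
            assert row["p_value"] == pytest.approx(
                res.p_values[res.gene_ids.index(gene)], rel=1e-5
            )
        # sorted by ascending p then rank
        assert list(df["p_value"]) == sorted(df["p_value"])

    def test_byte_identical_across_repeat_runs(self, mini_world):
        onto, db, net = mini_world
        outs = []
        for _ in range(2):
            res = phenorank("dQ", RunConfig(n_sets=25, rng_seed=5), db, net, onto)
            buf = io.StringIO()
            write_results(res, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]
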