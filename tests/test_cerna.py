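"""Immune filtering, ceRNA assembly, degree ranking and validation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cernapipe.cerna import (
    PredictionDB,
    assemble_cerna,
    audit_network,
    coexpression_pairs,
    consensus_mir_mrna,
    degree_rank,
    filter_lnc_mir,
    immune_filter,
    intersect_top_genes,
    validate_key_genes,
)
from cernapipe.cerna import PREDICTION_SOURCES
from cernapipe.errors import InvalidInputError


def _infiltration(rng, samples):
    vals = {ct: np.abs(rng.normal(1, 0.3, len(samples))) for ct in
            ("B_cell", "CD4_T", "CD8_T", "neutrophil", "macrophage", "dendritic")}
    return pd.DataFrame(vals, index=samples)


class TestImmuneFilter:
    def test_copy_of_abundance_kept(self, rng):
        samples = [f"s{i}" for i in range(50)]
        infil = _infiltration(rng, samples)
        expr = pd.DataFrame(
            {"gene_pos": infil["CD4_T"], "gene_neg": -infil["CD4_T"]}
        ).T
        expr.columns = samples
        out = immune_filter(expr, infil, "CD4_T")
        assert out.set_index("gene").loc["gene_pos", "rho"] == pytest.approx(1.0)
        # anti-correlated gene kept by the absolute-value rule
        assert bool(out.set_index("gene").loc["gene_neg", "kept"])

    def test_independent_gene_dropped(self, rng):
        samples = [f"s{i}" for i in range(300)]
        infil = _infiltration(rng, samples)
        expr = pd.DataFrame([rng.normal(size=300)], index=["g"], columns=samples)
        out = immune_filter(expr, infil, "CD8_T")
        assert not bool(out.iloc[0]["kept"])

    def test_unknown_cell_type(self, rng):
        samples = [f"s{i}" for i in range(20)]
        expr = pd.DataFrame([rng.normal(size=20)], index=["g"], columns=samples)
        with pytest.raises(InvalidInputError):
            immune_filter(expr, _infiltration(rng, samples), "NK_cell")


class TestCoexpression:
    def test_noisy_copy_kept_negative_dropped(self, rng):
        samples = [f"s{i}" for i in range(60)]
        m = rng.normal(size=60)
        mrna = pd.DataFrame([m], index=["M"], columns=samples)
        lnc = pd.DataFrame(
            [m + rng.normal(0, 0.1, 60), -m + rng.normal(0, 0.1, 60)],
            index=["Lpos", "Lneg"],
            columns=samples,
        )
        out = coexpression_pairs(lnc, mrna).set_index("lncRNA")
        assert bool(out.loc["Lpos", "kept"])
        assert not bool(out.loc["Lneg", "kept"])  # positive co-expression only

    def test_underpowered_pair_dropped_by_bh(self, rng):
        # r ~ 0.7 at n=10 in a grid of null pairs: raw p ~ 0.02 but BH over
        # the grid pushes adj_p above 0.05
        samples = [f"s{i}" for i in range(10)]
        m = rng.normal(size=10)
        lnc_rows = {"L0": 0.72 * m + rng.normal(0, 0.65, 10)}
        for i in range(1, 15):
            lnc_rows[f"L{i}"] = rng.normal(size=10)
        lnc = pd.DataFrame(lnc_rows).T
        lnc.columns = samples
        mrna = pd.DataFrame([m], index=["M"], columns=samples)
        out = coexpression_pairs(lnc, mrna).set_index("lncRNA")
        row = out.loc["L0"]
        if row["r"] > 0.7:  # guard: the construction is stochastic
            assert row["adj_p"] > row["p"]
            assert not bool(row["kept"]) or row["adj_p"] < 0.05

    def test_empty_inputs(self, rng):
        samples = [f"s{i}" for i in range(12)]
        empty = pd.DataFrame(np.empty((0, 12)), columns=samples)
        mrna = pd.DataFrame([rng.normal(size=12)], index=["M"], columns=samples)
        out = coexpression_pairs(empty, mrna)
        assert len(out) == 0


def _db(lnc_mir_rows, mir_mrna_rows):
    lm = pd.DataFrame(lnc_mir_rows, columns=["lncRNA", "miRNA", "score"])
    mm_rows = []
    for mir, mrna, n_src in mir_mrna_rows:
        flags = {s: (1 if i < n_src else 0) for i, s in enumerate(PREDICTION_SOURCES)}
        mm_rows.append({"miRNA": mir, "mRNA": mrna, **flags})
    mm = pd.DataFrame(mm_rows, columns=["miRNA", "mRNA", *PREDICTION_SOURCES])
    return PredictionDB(lm, mm)


class TestPredictionFilters:
    def test_score_threshold_strict(self):
        db = _db([("L", "m1", 0.95), ("L", "m2", 0.9)], [])
        out = filter_lnc_mir(db)
        assert out["miRNA"].tolist() == ["m1"]

    def test_consensus_source_counts(self):
        db = _db([], [("m", "M1", 6), ("m", "M2", 5), ("m", "M3", 4)])
        out = consensus_mir_mrna(db, min_sources=5)
        assert sorted(out["mRNA"]) == ["M1", "M2"]
        strict = consensus_mir_mrna(db, min_sources=6)
        assert sorted(strict["mRNA"]) == ["M1"]

    def test_empty_db(self):
        db = _db([], [])
        assert len(filter_lnc_mir(db)) == 0
        assert len(consensus_mir_mrna(db)) == 0


def _coexpr_frame(pairs):
    return pd.DataFrame(
        [{"lncRNA": l, "mRNA": m, "r": r, "adj_p": 0.001, "kept": kept}
         for l, m, r, kept in pairs]
    )


def _lnc_mir_frame(pairs):
    return pd.DataFrame([{"lncRNA": l, "miRNA": m, "score": s} for l, m, s in pairs])


def _mir_mrna_frame(pairs):
    return pd.DataFrame([{"miRNA": m, "mRNA": g, "db_count": c} for m, g, c in pairs])


class TestAssembleCerna:
    def test_single_triad(self):
        net = assemble_cerna(
            _coexpr_frame([("L", "M", 0.8, True)]),
            _lnc_mir_frame([("L", "m", 0.95)]),
            _mir_mrna_frame([("m", "M", 6)]),
        )
        assert net.triads == [("L", "m", "M")]
        assert net.n_edges == 3

    def test_failed_coexpression_blocks_triad(self):
        net = assemble_cerna(
            _coexpr_frame([("L", "M", 0.6, False)]),
            _lnc_mir_frame([("L", "m", 0.95)]),
            _mir_mrna_frame([("m", "M", 6)]),
        )
        assert net.triads == []

    def test_shared_edge_deduplicated(self):
        net = assemble_cerna(
            _coexpr_frame([("L", "M", 0.8, True)]),
            _lnc_mir_frame([("L", "m1", 0.95), ("L", "m2", 0.92)]),
            _mir_mrna_frame([("m1", "M", 6), ("m2", "M", 5)]),
        )
        assert len(net.triads) == 2
        # L-M co-expression edge appears once; 2 triads share it
        coexpr_edges = [
            (u, v) for u, v, d in net.graph.edges(data=True)
            if d["edge_type"] == "lnc_mrna_coexpr"
        ]
        assert len(coexpr_edges) == 1

    def test_brute_force_triple_loop_oracle(self, rng):
        for trial in range(5):
            lncs = [f"L{i}" for i in range(10)]
            mirs = [f"m{i}" for i in range(15)]
            mrnas = [f"M{i}" for i in range(10)]
            coexpr, lm, mm = [], [], []
            coexpr_set, lm_set, mm_set = set(), set(), set()
            for l, M in itertools.product(lncs, mrnas):
                if rng.random() < 0.25:
                    coexpr.append((l, M, 0.8, True))
                    coexpr_set.add((l, M))
            for l, m in itertools.product(lncs, mirs):
                if rng.random() < 0.2:
                    lm.append((l, m, 0.95))
                    lm_set.add((l, m))
            for m, M in itertools.product(mirs, mrnas):
                if rng.random() < 0.2:
                    mm.append((m, M, 6))
                    mm_set.add((m, M))
            expected = sorted(
                (l, m, M)
                for l, m, M in itertools.product(lncs, mirs, mrnas)
                if (l, M) in coexpr_set and (l, m) in lm_set and (m, M) in mm_set
            )
            net = assemble_cerna(
                _coexpr_frame(coexpr), _lnc_mir_frame(lm), _mir_mrna_frame(mm)
            )
            assert net.triads == expected

    def test_audit_flags_corrupted_inputs(self):
        coexpr = _coexpr_frame([("L", "M", 0.8, True)])
        lm = _lnc_mir_frame([("L", "m", 0.95)])
        mm = _mir_mrna_frame([("m", "M", 6)])
        net = assemble_cerna(coexpr, lm, mm)
        assert audit_network(net, coexpr, lm, mm) == []
        corrupted = coexpr.assign(r=0.5)
        assert audit_network(net, corrupted, lm, mm)


class TestDegreeRank:
    def test_star_graph(self):
        pairs = [("c", "M", 0.8, True)]
        lm = _lnc_mir_frame([("c", f"m{i}", 0.95) for i in range(5)])
        mm = _mir_mrna_frame([(f"m{i}", "M", 6) for i in range(5)])
        net = assemble_cerna(_coexpr_frame(pairs), lm, mm)
        top = degree_rank(net, k=1)
        assert top.iloc[0]["node"] in ("c", "M")
        assert top.iloc[0]["degree"] == 6  # 5 miRNAs + the co-expression edge

    def test_tie_broken_lexicographically(self):
        net = assemble_cerna(
            _coexpr_frame([("B", "A", 0.8, True)]),
            _lnc_mir_frame([("B", "m", 0.95)]),
            _mir_mrna_frame([("m", "A", 6)]),
        )
        ranks = degree_rank(net)
        assert ranks.iloc[0]["node"] == "A"  # A and B both degree 2

    def test_k_larger_than_network(self):
        net = assemble_cerna(
            _coexpr_frame([("L", "M", 0.8, True)]),
            _lnc_mir_frame([("L", "m", 0.95)]),
            _mir_mrna_frame([("m", "M", 6)]),
        )
        assert len(degree_rank(net, k=100)) == 3

    def test_matches_naive_neighbor_count(self, rng, pipeline_results):
        net = pipeline_results["branches"]["cd4"]["network"]
        for node in net.graph.nodes:
            assert net.graph.degree(node) == len(set(net.graph.neighbors(node)))


class TestKeyGenes:
    def _top(self, names):
        return pd.DataFrame(
            {"node": names, "degree": range(len(names), 0, -1),
             "rank": range(1, len(names) + 1)}
        )

    def test_identical_lists(self):
        t = self._top([f"G{i}" for i in range(10)])
        assert intersect_top_genes(t, t) == [f"G{i}" for i in range(10)]

    def test_disjoint_lists(self):
        assert intersect_top_genes(self._top(["A", "B"]), self._top(["C", "D"])) == []

    def test_ordered_by_worse_rank(self):
        cd4 = self._top(["A", "B", "C"])
        cd8 = self._top(["C", "B", "A"])
        # worse ranks: A->3, B->2, C->3; ties lexicographic
        assert intersect_top_genes(cd4, cd8) == ["B", "A", "C"]


class TestValidateKeyGenes:
    def test_near_copy_is_significant(self, rng):
        expr = pd.DataFrame(
            {
                "ICOS": rng.normal(5, 1, 100),
            }
        ).T
        expr.loc["KEY"] = expr.loc["ICOS"] + rng.normal(0, 0.1, 100)
        out = validate_key_genes(["KEY"], "ICOS", {"c": expr})
        assert out.iloc[0]["r"] > 0.9 and bool(out.iloc[0]["significant"])

    def test_missing_gene_recorded(self, rng):
        expr = pd.DataFrame({"ICOS": rng.normal(size=50)}).T
        out = validate_key_genes(["ABSENT"], "ICOS", {"c": expr})
        assert out.iloc[0]["status"] == "missing"

    def test_planted_validation_correlation_recovered(self, bundle):
        out = validate_key_genes(
            bundle.truth.key_genes,
            bundle.truth.prognostic_gene,
            bundle.validation_cohorts,
        )
        ok = out[out["status"] == "ok"]
        assert len(ok) == len(bundle.truth.key_genes) * 2
        target = bundle.config.validation_rho
        assert np.all(np.abs(ok["r"] - target) < 0.15)


class TestBranchIndependence:
    def test_cd4_outputs_unchanged_by_cd8_permutation(self, bundle, rng):
        """Permuting the CD8 abundance column never changes the CD4 branch."""
        de_genes = bundle.truth.de_mrna_up[:20]
        expr = bundle.expression.values.loc[de_genes]
        infil = bundle.infiltration
        shuffled = infil.copy()
        shuffled["CD8_T"] = rng.permutation(shuffled["CD8_T"].to_numpy())
        a = immune_filter(expr, infil, "CD4_T")
        b = immune_filter(expr, shuffled, "CD4_T")
        pd.testing.assert_frame_equal(a, b)
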