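"""Probe collapsing, biotype partition and moderated-t DE tests."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from cernapipe.diffexpr import (
    ExpressionMatrix,
    collapse_probes,
    de_table,
    ebayes_moderate,
    fit_group_model,
    partition_biotype,
    select_de,
)
from cernapipe.errors import InsufficientDataError, InvalidInputError


def _matrix(values, genes=None, samples=None, biotype=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    bt = pd.Series(biotype, index=genes) if biotype else None
    return ExpressionMatrix(df, bt)


class TestCollapseProbes:
    def test_mean_over_probes(self):
        probes = pd.DataFrame(
            [[2.0, 1.0], [4.0, 3.0], [7.0, 7.0]],
            index=["p1", "p2", "p3"],
            columns=["s1", "s2"],
        )
        mapping = pd.Series({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        out = collapse_probes(probes, mapping)
        assert out.loc["GENE1", "s1"] == 3.0
        assert out.loc["GENE2", "s1"] == 7.0  # single probe passes through

    def test_unmapped_probe_dropped(self):
        probes = pd.DataFrame([[1.0], [2.0]], index=["p1", "px"], columns=["s1"])
        out = collapse_probes(probes, pd.Series({"p1": "GENE1"}))
        assert list(out.index) == ["GENE1"]

    def test_empty_mapping_raises(self):
        probes = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with pytest.raises(InvalidInputError):
            collapse_probes(probes, pd.Series(dtype=object))


class TestPartitionBiotype:
    def test_category_assignment(self):
        m = _matrix(
            np.zeros((4, 2)),
            genes=["a", "b", "c", "d"],
            biotype=["protein coding", "lincRNA", "antisense", "pseudogene"],
        )
        mrna, lnc = partition_biotype(m)
        assert list(mrna.genes) == ["a"]  # space-normalized 'protein coding'
        assert list(lnc.genes) == ["b", "c"]

    def test_partition_is_disjoint_and_excludes_other(self, bundle):
        mrna, lnc = partition_biotype(bundle.expression)
        assert not set(mrna.genes) & set(lnc.genes)
        total = len(mrna.genes) + len(lnc.genes)
        assert total < len(bundle.expression.genes)  # pseudogenes excluded

    def test_requires_annotation(self):
        with pytest.raises(InvalidInputError):
            partition_biotype(_matrix(np.zeros((2, 2))))


class TestFitGroupModel:
    def test_logfc_is_mean_difference(self, rng):
        x = rng.normal(size=(30, 12))
        high = np.array([True] * 5 + [False] * 7)
        df = pd.DataFrame(x)
        fit = fit_group_model(df, high)
        expected = x[:, :5].mean(axis=1) - x[:, 5:].mean(axis=1)
        np.testing.assert_allclose(fit["logFC"], expected, atol=1e-12)

    def test_zero_variance_case(self):
        df = pd.DataFrame([[4.0, 4.0, 2.0, 2.0]] * 12)
        fit = fit_group_model(df, [True, True, False, False])
        assert fit["logFC"].iloc[0] == 2.0
        assert fit["s2"].iloc[0] == 0.0

    def test_label_swap_flips_sign(self, rng):
        x = pd.DataFrame(rng.normal(size=(15, 10)))
        high = np.array([True] * 5 + [False] * 5)
        a = fit_group_model(x, high)
        b = fit_group_model(x, ~high)
        np.testing.assert_allclose(a["logFC"], -b["logFC"], atol=1e-12)
        np.testing.assert_allclose(a["s2"], b["s2"], atol=1e-12)

    def test_small_group_raises(self, rng):
        x = pd.DataFrame(rng.normal(size=(15, 5)))
        with pytest.raises(InsufficientDataError):
            fit_group_model(x, [True, False, False, False, False])


class TestEbayes:
    def test_full_shrinkage_limit_homogeneous_variances(self, rng):
        # equal true variances: prior df -> inf, all genes tested against s0^2
        x = pd.DataFrame(rng.normal(0, 1, size=(2000, 16)))
        high = np.array([True] * 8 + [False] * 8)
        fit = ebayes_moderate(fit_group_model(x, high))
        if np.isinf(fit.attrs["prior_df"]):
            assert fit["s2_post"].nunique() == 1
        else:
            assert fit.attrs["prior_df"] > 20  # heavy shrinkage

    def test_no_shrinkage_limit_heterogeneous_variances(self, rng):
        # wildly heterogeneous variances: prior df -> 0, moderated t ~ ordinary t
        scale = np.exp(rng.normal(0, 5, size=500))
        x = pd.DataFrame(rng.normal(0, 1, size=(500, 12)) * scale[:, None])
        high = np.array([True] * 6 + [False] * 6)
        base = fit_group_model(x, high)
        fit = ebayes_moderate(base)
        assert fit.attrs["prior_df"] < 1.0
        ordinary_t = base["logFC"] / np.sqrt(base["s2"] * base["stdev_unscaled"] ** 2)
        ratio = fit["t_mod"] / ordinary_t
        assert np.nanmedian(np.abs(ratio - 1)) < 0.05

    def test_matches_r_limma(self, rng, tmp_path):
        x = rng.normal(5, 1, size=(60, 12)) * rng.uniform(0.5, 2, 60)[:, None]
        x[:5, :6] += 2.0
        vals = pd.DataFrame(
            x, index=[f"g{i}" for i in range(60)], columns=[f"s{i}" for i in range(12)]
        )
        high = np.array([True] * 6 + [False] * 6)
        mine = ebayes_moderate(fit_group_model(vals, high))
        infile = tmp_path / "in.tsv"
        outfile = tmp_path / "out.tsv"
        vals.to_csv(infile, sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{infile}", row.names=1))
        design <- cbind(Intercept=1, High=c(rep(1,6), rep(0,6)))
        fit <- eBayes(lmFit(x, design), trend=FALSE)
        out <- data.frame(logFC=fit$coefficients[,"High"], t=fit$t[,"High"],
                          p=fit$p.value[,"High"], d0=fit$df.prior)
        write.table(out, "{outfile}", sep="\\t", quote=FALSE)
        """
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(outfile, sep="\t")
        assert mine.attrs["prior_df"] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(mine["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-6, atol=1e-12)

    def test_p_monotone_in_abs_t(self, rng):
        x = pd.DataFrame(rng.normal(size=(300, 10)))
        x.iloc[:30, :5] += rng.uniform(0.5, 3, size=(30, 5))
        fit = ebayes_moderate(fit_group_model(x, [True] * 5 + [False] * 5))
        order = np.argsort(-np.abs(fit["t_mod"].to_numpy()))
        p_sorted = fit["p"].to_numpy()[order]
        assert np.all(np.diff(p_sorted) >= -1e-12)


class TestSelectDE:
    @pytest.mark.parametrize(
        "adj_p, logfc, expected",
        [
            (0.04, 2.5, "up"),
            (0.04, 2.0, "ns"),     # strict > on the fold-change threshold
            (0.05, 3.0, "ns"),     # strict < on the adjusted p threshold
            (0.01, -2.5, "down"),
        ],
    )
    def test_strict_thresholds(self, adj_p, logfc, expected):
        frame = pd.DataFrame({"adj_p": [adj_p], "logFC": [logfc]}, index=["g"])
        up, down = select_de(frame)
        got = "up" if "g" in up else ("down" if "g" in down else "ns")
        assert got == expected

    def test_de_table_direction_consistent(self, bundle):
        from cernapipe.survival import split_by_median

        mrna, _ = partition_biotype(bundle.expression)
        high = split_by_median(
            bundle.expression.values.loc[bundle.truth.prognostic_gene].to_numpy()
        )
        table = de_table(mrna.values, high)
        up, down = select_de(table)
        assert set(up) == set(table.index[table["direction"] == "up"])
        assert set(down) == set(table.index[table["direction"] == "down"])
        assert (table["adj_p"] >= table["p"] - 1e-15).all()
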