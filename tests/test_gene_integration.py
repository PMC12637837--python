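import numpy as np
import pandas as pd
import pytest

from epimet import (
    ValidationError,
    classify_genes,
    concordance_filter,
    de_genes,
    filter_low_expression,
    integrate,
    log_norm,
    size_factors,
    standin_de_test,
)


def _counts_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "n_hyper", "n_hypo"])


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "n_hyper,n_hypo,expected",
        [
            (0, 2, "hypo"),
            (2, 0, "hyper"),
            (1, 1, "mixed"),
            (0, 1, "none"),
            (1, 0, "none"),
            (0, 0, "none"),
            (3, 2, "mixed"),
        ],
    )
    def test_class_rules(self, n_hyper, n_hypo, expected):
        calls = classify_genes(_counts_df([("G1", n_hyper, n_hypo)]))
        assert calls.loc[0, "meth_class"] == expected

    def test_class_invariant_holds_on_random_counts(self, rng):
        df = _counts_df(
            [(f"G{i}", int(rng.integers(0, 4)), int(rng.integers(0, 4))) for i in range(200)]
        )
        calls = classify_genes(df)
        total = calls["n_hyper"] + calls["n_hypo"]
        none = calls["meth_class"] == "none"
        assert ((total < 2) == none).all()


class TestConcordance:
    def _calls(self, mapping):
        return classify_genes(
            _counts_df(
                [
                    (g, {"hypo": (0, 2), "hyper": (2, 0), "mixed": (1, 1)}[c][0],
                     {"hypo": (0, 2), "hyper": (2, 0), "mixed": (1, 1)}[c][1])
                    for g, c in mapping.items()
                ]
            )
        )

    def test_identical_classes_concordant(self):
        out = concordance_filter(self._calls({"G1": "hypo"}), self._calls({"G1": "hypo"}))
        assert out.loc[0, "status"] == "concordant"

    def test_opposite_classes_discordant(self):
        out = concordance_filter(self._calls({"G1": "hypo"}), self._calls({"G1": "hyper"}))
        assert out.loc[0, "status"] == "discordant"

    def test_mixed_must_match_mixed(self):
        out = concordance_filter(self._calls({"G1": "mixed"}), self._calls({"G1": "hypo"}))
        assert out.loc[0, "status"] == "discordant"

    def test_set_arithmetic_partition(self):
        a = self._calls({"A": "hypo", "B": "hypo", "C": "hypo"})
        b = self._calls({"B": "hypo", "C": "hyper", "D": "mixed"})
        out = concordance_filter(a, b).set_index("gene_id")
        assert out.loc["B", "status"] == "concordant"
        assert out.loc["C", "status"] == "discordant"
        assert set(out.index[out["status"] == "unshared"]) == {"A", "D"}

    def test_partition_identity_on_random_classes(self, rng):
        genes_a = [f"G{i}" for i in rng.choice(100, 60, replace=False)]
        genes_b = [f"G{i}" for i in rng.choice(100, 60, replace=False)]
        a = self._calls({g: rng.choice(["hypo", "hyper", "mixed"]) for g in genes_a})
        b = self._calls({g: rng.choice(["hypo", "hyper", "mixed"]) for g in genes_b})
        out = concordance_filter(a, b)
        assert set(out["gene_id"]) == set(genes_a) | set(genes_b)
        n = out["status"].value_counts()
        assert n.sum() == len(out)


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(c)
        assert f.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_all_one(self):
        c = pd.DataFrame({"s1": [10, 20], "s2": [10, 20], "s3": [10, 20]})
        assert size_factors(c).to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_single_sample_factor_one(self):
        assert size_factors(pd.DataFrame({"s1": [5, 7]})).to_numpy() == pytest.approx([1.0])

    def test_scaled_copies_proportional_with_geometric_mean_one(self, rng):
        base = rng.integers(10, 1000, 50).astype(float)
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        c = pd.DataFrame({f"s{i}": base * s for i, s in enumerate(scales)})
        f = size_factors(c).to_numpy()
        expected = scales / np.exp(np.mean(np.log(scales)))
        assert f == pytest.approx(expected)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_zero_containing_genes_excluded_from_reference(self):
        c = pd.DataFrame({"s1": [0, 10, 20], "s2": [100, 10, 20]})
        f = size_factors(c)
        assert f.to_numpy() == pytest.approx([1.0, 1.0])

    def test_no_all_positive_gene_raises(self):
        c = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValidationError):
            size_factors(c)

    def test_agrees_with_external_deseq_normalisation(self, rng):
        """Cross-check against an independent median-of-ratios implementation."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(80, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        f = size_factors(counts)
        _, ref = pydeseq2.deseq2_norm(counts.T)  # pydeseq2 is samples x genes
        # pydeseq2 takes the median in log space; with an even gene count the
        # interpolated middle differs in the 4th decimal from the ratio-space
        # median used here
        assert f.to_numpy() == pytest.approx(np.asarray(ref), rel=1e-3)


class TestExpressionUtilities:
    def test_base_mean_filter_is_strict(self):
        de = pd.DataFrame(
            {
                "gene_id": list("ABCDE"),
                "base_mean": [5.0, 10.0, 20.0, 21.0, 100.0],
                "log2fc": [0.0] * 5,
                "p_value": [0.5] * 5,
            }
        )
        kept = filter_low_expression(de)
        assert list(kept["gene_id"]) == ["D", "E"]

    def test_boundary_just_above_threshold_retained(self):
        de = pd.DataFrame(
            {"gene_id": ["A"], "base_mean": [20.5], "log2fc": [0.0], "p_value": [0.5]}
        )
        assert len(filter_low_expression(de)) == 1

    @pytest.mark.parametrize(
        "count,factor,expected",
        [(7, 1.0, 3.0), (0, 2.5, 0.0), (10, 2.0, np.log2(6))],
    )
    def test_log_norm_values(self, count, factor, expected):
        out = log_norm(pd.DataFrame({"s": [count]}), pd.Series({"s": factor}))
        assert out.iloc[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (1.0, 0.01, "none"),   # boundary fails strict >
            (2.3, 0.004, "up"),
            (-1.5, 0.2, "none"),
            (-1.5, 0.01, "down"),
            (0.5, 0.001, "none"),
        ],
    )
    def test_de_gene_rule(self, lfc, p, expected):
        de = pd.DataFrame(
            {"gene_id": ["A"], "base_mean": [100.0], "log2fc": [lfc], "p_value": [p]}
        )
        assert de_genes(de).loc[0, "expression_direction"] == expected


class TestStandinDeTest:
    def _groups(self, labels):
        return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])

    def test_identical_groups_zero_lfc(self, rng):
        block = rng.integers(50, 500, size=(30, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]), columns=[f"s{i}" for i in range(6)]
        )
        out = standin_de_test(counts, self._groups(["PT"] * 3 + ["LU"] * 3), "LU", "PT")
        assert out["log2fc"].abs().max() < 1e-9

    def test_planted_fourfold_change_recovered(self, rng):
        n_genes, n_planted = 60, 8
        mu = np.full(n_genes, 400.0)
        mu_tgt = mu.copy()
        mu_tgt[:n_planted] *= 4.0  # 4-fold change in a minority of genes
        r = 50.0  # low dispersion
        ref = rng.negative_binomial(r, r / (r + mu[:, None]), (n_genes, 6))
        tgt = rng.negative_binomial(r, r / (r + mu_tgt[:, None]), (n_genes, 6))
        counts = pd.DataFrame(
            np.hstack([ref, tgt]), columns=[f"s{i}" for i in range(12)]
        )
        out = standin_de_test(counts, self._groups(["PT"] * 6 + ["LU"] * 6), "LU", "PT")
        planted_lfc = out["log2fc"].to_numpy()[:n_planted]
        assert planted_lfc == pytest.approx(np.full(n_planted, 2.0), abs=0.5)
        assert np.median(np.abs(out["log2fc"].to_numpy()[n_planted:])) < 0.3

    def test_all_zero_gene_has_zero_base_mean(self):
        counts = pd.DataFrame(
            {"s0": [0, 10], "s1": [0, 12], "s2": [0, 9], "s3": [0, 11]},
            index=["dead", "alive"],
        )
        out = standin_de_test(counts, self._groups(["PT", "PT", "LU", "LU"]), "LU", "PT")
        row = out.set_index("gene_id").loc["dead"]
        assert row["base_mean"] == 0.0
        assert len(filter_low_expression(out)) == 0 or "dead" not in set(
            filter_low_expression(out)["gene_id"]
        )


class TestIntegrate:
    def _conc(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "class_a", "class_b", "status"])

    def _expr(self, mapping):
        return pd.DataFrame(
            {"gene_id": list(mapping), "expression_direction": list(mapping.values())}
        )

    @pytest.mark.parametrize(
        "meth,direction,expected",
        [
            ("hypo", "up", True),
            ("hypo", "down", False),
            ("hyper", "down", True),
            ("hyper", "up", False),
            ("mixed", "up", False),
            ("hypo", "none", False),
        ],
    )
    def test_flag_rule(self, meth, direction, expected):
        out = integrate(
            self._conc([("G1", meth, meth, "concordant")]), self._expr({"G1": direction})
        )
        assert bool(out.loc[0, "epigenetically_regulated"]) is expected

    def test_discordant_gene_never_flagged(self):
        out = integrate(
            self._conc([("G1", "hypo", "hyper", "discordant")]), self._expr({"G1": "up"})
        )
        assert not out.loc[0, "epigenetically_regulated"]
        assert not out.loc[0, "concordant"]

    def test_invariant_on_synthetic_truth(self, tiny_sim):
        """Flag implies concordance and opposing methylation/expression."""
        from epimet import call_dms, assign_probes, build_promoters, count_promoter_dms

        ann = assign_probes(
            tiny_sim.manifest, build_promoters(tiny_sim.transcripts), tiny_sim.states
        )
        calls = {}
        for cohort in tiny_sim.config.cohorts:
            dms = call_dms(tiny_sim.betas[cohort], tiny_sim.sheets[cohort])
            calls[cohort] = classify_genes(count_promoter_dms(dms, ann))
        conc = concordance_filter(calls["XEN"], calls["AUR"])
        dirs = de_genes(filter_low_expression(tiny_sim.de_table))
        out = integrate(conc, dirs)
        flagged = out[out["epigenetically_regulated"]]
        assert (flagged["concordant"]).all()
        ok = ((flagged["class_a"] == "hypo") & (flagged["expression_direction"] == "up")) | (
            (flagged["class_a"] == "hyper") & (flagged["expression_direction"] == "down")
        )
        assert ok.all()
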