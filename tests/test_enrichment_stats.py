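from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from epimet import (
    GeneSetCollection,
    chromosome_enrichment,
    context_enrichment,
    fisher_2x2,
    odds_ratio,
    or_confidence_interval,
    ora,
)
from epimet.dms_calling import call_dms
from epimet.genomic_annotation import assign_probes, build_promoters


def hypergeom_two_sided_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p: sum of hypergeometric probabilities
    of all tables with the observed margins that are no more probable than
    the observed one."""
    r, cs, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, cs - (n - r)), min(r, cs)
    denom = comb(n, cs)
    pmf = {x: Fraction(comb(r, x) * comb(n - r, cs - x), denom) for x in range(lo, hi + 1)}
    pobs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= pobs))


class TestFisher:
    def test_proportional_table_is_null(self):
        or_, p = fisher_2x2(10, 90, 10, 90)
        assert or_ == 1.0 and p == 1.0

    def test_worked_cross_product(self):
        or_, p = fisher_2x2(30, 70, 70, 830)
        assert or_ == pytest.approx(24900 / 4900)
        assert p == pytest.approx(hypergeom_two_sided_oracle(30, 70, 70, 830), rel=1e-9)

    def test_zero_cell_odds_ratio(self):
        or_, _ = fisher_2x2(0, 10, 10, 10)
        assert or_ == 0.0
        or_inf, _ = fisher_2x2(10, 0, 10, 10)
        assert np.isinf(or_inf)

    def test_matches_exact_oracle_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_2x2(a, b, c, d)
            assert p == pytest.approx(hypergeom_two_sided_oracle(a, b, c, d), abs=1e-10)

    def test_or_invariance_under_simultaneous_swap(self, rng):
        a, b, c, d = rng.integers(1, 50, 4)
        assert odds_ratio(a, b, c, d) == pytest.approx(odds_ratio(d, c, b, a))
        assert odds_ratio(c, d, a, b) == pytest.approx(1 / odds_ratio(a, b, c, d))

    def test_negative_cell_rejected(self):
        from epimet import ValidationError

        with pytest.raises(ValidationError):
            fisher_2x2(-1, 2, 3, 4)


class TestConfidenceInterval:
    def test_worked_woolf_interval(self):
        lo, hi = or_confidence_interval(30, 70, 70, 830)
        se = np.sqrt(1 / 30 + 1 / 70 + 1 / 70 + 1 / 830)
        assert lo == pytest.approx(np.exp(np.log(24900 / 4900) - 1.959964 * se), rel=1e-4)
        assert hi == pytest.approx(np.exp(np.log(24900 / 4900) + 1.959964 * se), rel=1e-4)
        assert (lo, hi) == pytest.approx((3.106, 8.315), abs=0.01)

    def test_null_table_interval_straddles_one(self):
        lo, hi = or_confidence_interval(10, 90, 10, 90)
        assert lo < 1.0 < hi

    def test_interval_brackets_odds_ratio(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(1, 60, 4)
            lo, hi = or_confidence_interval(a, b, c, d)
            assert lo <= odds_ratio(a, b, c, d) <= hi

    def test_haldane_correction_at_zero_cell(self):
        lo, hi = or_confidence_interval(0, 10, 10, 10)
        assert 0 < lo < hi < np.inf


class TestChromosomeEnrichment:
    def _dms(self, probe_ids, flagged):
        return pd.DataFrame(
            {
                "probe_id": probe_ids,
                "is_dms": [p in flagged for p in probe_ids],
                "direction": ["hypo" if p in flagged else "none" for p in probe_ids],
            }
        )

    def _manifest(self, chroms):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i:05d}" for i in range(len(chroms))],
                "chromosome": chroms,
                "position": np.arange(1, len(chroms) + 1),
                "cpg_context": ["open_sea"] * len(chroms),
            }
        )

    def test_worked_arithmetic(self, rng):
        manifest = self._manifest(["chrA"] * 100 + ["chrB"] * 900)
        dms_on_a = [f"cg{i:05d}" for i in range(30)]
        dms_on_b = [f"cg{i:05d}" for i in range(100, 170)]
        dms = self._dms(list(manifest["probe_id"]), set(dms_on_a + dms_on_b))
        rows = chromosome_enrichment(dms, manifest).set_index("category")
        a_row = rows.loc["chrA"]
        assert (a_row["a"], a_row["b"], a_row["c"], a_row["d"]) == (30, 70, 70, 830)
        assert a_row["expected_dms"] == pytest.approx(10.0)
        assert a_row["odds_ratio"] == pytest.approx(24900 / 4900)

    def test_degenerate_all_dms_on_one_chromosome(self):
        manifest = self._manifest(["chr1"] * 100 + ["chr2"] * 100)
        flagged = {f"cg{i:05d}" for i in range(50)}
        rows = chromosome_enrichment(
            self._dms(list(manifest["probe_id"]), flagged), manifest
        ).set_index("category")
        assert np.isinf(rows.loc["chr1", "odds_ratio"])
        assert rows.loc["chr2", "odds_ratio"] == 0.0
        assert rows["degenerate"].all()

    def test_uniform_thinning_gives_null_ors(self, rng):
        chroms = rng.choice([f"chr{i}" for i in range(1, 6)], 5000)
        manifest = self._manifest(list(chroms))
        flagged = set(rng.choice(manifest["probe_id"], 500, replace=False))
        rows = chromosome_enrichment(self._dms(list(manifest["probe_id"]), flagged), manifest)
        assert rows["odds_ratio"].between(0.5, 2.0).all()
        assert (rows["q_value"] > 0.05).all()


class TestContextEnrichment:
    def test_planted_open_sea_hyper_enrichment(self, rng):
        """Hyper DMS planted only in open-sea probes show OR > 1 there and
        depletion in islands."""
        n = 4000
        contexts = rng.choice(["island", "open_sea"], n, p=[0.5, 0.5])
        probe_ids = [f"cg{i:05d}" for i in range(n)]
        annotation = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "cpg_context": contexts,
                "chromatin_state": ["other"] * n,
                "promoter_hits": [[]] * n,
            }
        )
        open_sea_ids = [p for p, c in zip(probe_ids, contexts) if c == "open_sea"]
        flagged = set(rng.choice(open_sea_ids, 150, replace=False))
        dms = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "is_dms": [p in flagged for p in probe_ids],
                "direction": ["hyper" if p in flagged else "none" for p in probe_ids],
            }
        )
        rows = context_enrichment(dms, annotation, direction="hyper").set_index("category")
        assert rows.loc["open_sea", "odds_ratio"] > 1
        assert rows.loc["open_sea", "q_value"] < 0.05
        assert rows.loc["island", "odds_ratio"] < 1

    def test_zero_dms_direction_rows_degenerate_not_raising(self, tiny_sim):
        annotation = assign_probes(
            tiny_sim.manifest, build_promoters(tiny_sim.transcripts), tiny_sim.states
        )
        dms = call_dms(tiny_sim.betas["XEN"], tiny_sim.sheets["XEN"])
        dms = dms.assign(
            direction=np.where(dms["direction"] == "hyper", "none", dms["direction"]),
            is_dms=dms["direction"] == "hypo",
        )
        rows = context_enrichment(dms, annotation, direction="hyper")
        assert rows["degenerate"].all()
        assert (rows["a"] == 0).all()

    def test_categories_partition_direction_dms(self, tiny_sim):
        annotation = assign_probes(
            tiny_sim.manifest, build_promoters(tiny_sim.transcripts), tiny_sim.states
        )
        dms = call_dms(tiny_sim.betas["XEN"], tiny_sim.sheets["XEN"])
        for facet in ("cpg_context", "chromatin_state"):
            for direction in ("hyper", "hypo"):
                rows = context_enrichment(dms, annotation, facet=facet, direction=direction)
                assert rows["a"].sum() == (dms["direction"] == direction).sum()


class TestOra:
    def test_worked_tail_sum(self):
        universe = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10", "g11"}  # k=4 of K=5, n=6
        sets = GeneSetCollection({"S": frozenset(members)})
        rows = ora(query, sets, universe)
        assert rows.loc[0, "p_value"] == pytest.approx(540 / 38760, rel=1e-9)
        assert rows.loc[0, "a"] == 4

    def test_zero_overlap_row_emitted_with_larger_p(self):
        universe = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection({"S": frozenset({f"g{i}" for i in range(5)})})
        hit = ora({"g0", "g1"}, sets, universe).loc[0, "p_value"]
        miss = ora({"g10", "g11"}, sets, universe).loc[0, "p_value"]
        assert miss == pytest.approx(1.0) or miss > hit

    def test_query_equals_universe_saturates(self):
        universe = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection({"S": frozenset({"g0", "g1", "g2"})})
        rows = ora(universe, sets, universe)
        assert rows.loc[0, "a"] == 3
        assert rows.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        from epimet import ValidationError

        sets = GeneSetCollection({"S": frozenset({"g0"})})
        with pytest.raises(ValidationError):
            ora({"alien"}, sets, {"g0", "g1"})
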