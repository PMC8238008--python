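"""DE filtering, BH correction, tallies, GO enrichment and qPCR ratios."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import hypergeom_tail_enum
from kinomics import expression as expr


def _de_table(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "log2FC", "p",
                                       "fdr"])


class TestDeFilter:
    def test_boundary_log2fc_is_not_de(self):
        table = _de_table([("t1", 1.0, 0.01, 0.01)])
        out = expr.de_filter(table)
        assert list(out["call"]) == ["ns"]

    def test_clear_up_and_down(self):
        table = _de_table([("t1", 2.0, 0.01, 0.01),
                           ("t2", -2.0, 0.01, 0.01),
                           ("t3", 2.0, 0.2, 0.01),
                           ("t4", 2.0, 0.01, 0.2)])
        out = expr.de_filter(table)
        assert list(out["call"]) == ["up", "down", "ns", "ns"]

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="fdr"):
            expr.de_filter(pd.DataFrame({"log2FC": [1], "p": [0.1]}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(-5, 5, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False)), min_size=1, max_size=40))
    def test_calls_partition_table(self, rows):
        table = _de_table([(f"t{i}", *r) for i, r in enumerate(rows)])
        out = expr.de_filter(table)
        counts = out["call"].value_counts()
        assert counts.sum() == len(rows)
        assert set(out["call"]) <= {"up", "down", "ns"}


class TestBhFdr:
    def test_stepup_hand_computation(self):
        q = expr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_and_single(self):
        assert np.allclose(expr.bh_fdr([0.2, 0.2, 0.2]), 0.2)
        assert np.allclose(expr.bh_fdr([0.37]), [0.37])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            expr.bh_fdr([0.1, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 60)))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(expr.bh_fdr(p), ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=30))
    def test_adjusted_never_below_raw_and_order_free(self, p):
        q = expr.bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        perm = list(reversed(range(len(p))))
        q_perm = expr.bh_fdr([p[i] for i in perm])
        assert np.allclose(q_perm, [q[i] for i in perm])


class TestTallyAndCrosstalk:
    CATALOG = pd.DataFrame({
        "protein_id": ["a", "b", "c"],
        "family": ["F1", "F1", "F2"],
        "group": ["F1", "F1", "F2"],
        "n_domains": [1, 1, 1],
        "status": ["bona_fide"] * 3})

    def test_three_up_in_one_family(self):
        de = pd.DataFrame({
            "transcript_id": ["a", "b", "a2"], "treatment": ["t1"] * 3,
            "call": ["up"] * 3})
        out = expr.family_tally(
            self.CATALOG, de,
            transcript_to_protein=lambda t: t.rstrip("2"))
        row = out[(out["family"] == "F1") & (out["call"] == "up")]
        # 'a' counted once per distinct transcript id
        assert row.iloc[0]["n_transcripts"] == 3

    def test_counted_once_per_treatment(self):
        de = pd.DataFrame({
            "transcript_id": ["a", "a"], "treatment": ["t1", "t2"],
            "call": ["up", "up"]})
        out = expr.family_tally(self.CATALOG, de)
        assert len(out) == 2
        assert (out["n_transcripts"] == 1).all()

    def test_crosstalk_disjoint_and_identical(self):
        assert expr.crosstalk({"a": {"x"}, "b": {"y"}})["shared"] == set()
        out = expr.crosstalk({"a": {"x", "y"}, "b": {"x", "y"}})
        assert out["shared"] == {"x", "y"}

    def test_crosstalk_matches_bruteforce(self, rng):
        sets = {f"assay{i}": set(rng.choice(50, size=20, replace=False))
                for i in range(3)}
        out = expr.crosstalk(sets)
        brute = set(sets["assay0"])
        for s in sets.values():
            brute &= set(s)
        assert out["shared"] == brute
        for (a, b), inter in out["pairwise"].items():
            assert inter == sets[a] & sets[b]


class TestGoEnrichment:
    def test_exact_hypergeometric_example(self):
        ann = pd.DataFrame(
            [{"gene": f"g{i}", "term": "T1"} for i in range(5)]
            + [{"gene": f"g{i}", "term": "T2"} for i in range(20)])
        fg = {"g0", "g1", "g2", "g3", "g17"}
        res = expr.go_enrichment(fg, {f"g{i}" for i in range(20)}, ann)
        by_term = {r.term: r for r in res}
        assert by_term["T1"].p == pytest.approx(76 / 15504, abs=1e-12)

    def test_universal_term_p_is_one(self):
        ann = pd.DataFrame([{"gene": f"g{i}", "term": "ALL"}
                            for i in range(10)])
        res = expr.go_enrichment({"g0", "g1"},
                                 {f"g{i}" for i in range(10)}, ann)
        assert res[0].p == pytest.approx(1.0)
        assert not res[0].enriched

    def test_foreground_outside_background_raises(self):
        ann = pd.DataFrame([{"gene": "g0", "term": "T"}])
        with pytest.raises(ValueError, match="absent"):
            expr.go_enrichment({"zz"}, {"g0"}, ann)

    def test_planted_term_monte_carlo_detection_rate(self, bundle):
        """The generator's planted GO term (5x foreground annotation
        rate) reaches hypergeometric p < 0.05 in >= 95% of 100 seeded
        annotation draws."""
        from kinomics.simulate import SimConfig, gen_expression_tables

        cfg = SimConfig()
        transcripts = sorted(bundle.cds)
        detected = 0
        for seed in range(100):
            _, go, _, slice_ = gen_expression_tables(
                cfg, bundle.truth, transcripts, seed=5000 + seed)
            fg = slice_["planted_by_assay"][cfg.assays[-1]]
            res = expr.go_enrichment(fg, set(transcripts), go)
            term = bundle.truth.true_enriched_terms[0]
            p = next((r.p for r in res if r.term == term), 1.0)
            detected += p < 0.05
        assert detected >= 95


class TestRestRatio:
    def test_closed_form_ratio_two(self):
        res = expr.rest_ratio([24.0, 24.0, 24.0], [23.0, 23.0, 23.0],
                              [[20.0, 20.0, 20.0]], [[20.0, 20.0, 20.0]])
        assert res.ratio == pytest.approx(2.0)
        assert res.delta_ct_target == pytest.approx(1.0)

    def test_null_identity(self):
        cts = [24.0, 24.1, 23.9]
        res = expr.rest_ratio(cts, cts, [[20.0, 20.1, 19.9]],
                              [[20.0, 20.1, 19.9]])
        assert res.ratio == pytest.approx(1.0)
        assert res.p_random == pytest.approx(1.0)

    def test_efficiency_must_exceed_one(self):
        with pytest.raises(ValueError, match="efficienc"):
            expr.rest_ratio([24, 24], [23, 23], [[20, 20]], [[20, 20]],
                            e_target=1.0)

    def test_percent_efficiency_conversion(self):
        assert expr.efficiency_from_percent(100.0) == 2.0
        assert expr.efficiency_from_percent(90.4) == pytest.approx(1.904)

    def test_global_ct_offset_leaves_ratio_unchanged(self, rng):
        ct_c = rng.uniform(22, 26, 3)
        ct_t = rng.uniform(22, 26, 3)
        rc = rng.uniform(18, 22, 3)
        rt = rng.uniform(18, 22, 3)
        base = expr.rest_ratio(ct_c, ct_t, [rc], [rt], seed=0)
        shift = expr.rest_ratio(ct_c + 3.0, ct_t + 3.0, [rc + 3.0],
                                [rt + 3.0], seed=0)
        assert shift.ratio == pytest.approx(base.ratio)

    def test_exhaustive_three_vs_three_matches_enumeration(self, rng):
        """p_random equals a from-scratch enumeration of all C(6,3)
        control reallocations."""
        ct_c = rng.normal(24, 0.3, 3)
        ct_t = rng.normal(22.8, 0.3, 3)
        rc = rng.normal(20, 0.2, 3)
        rt = rng.normal(20, 0.2, 3)
        res = expr.rest_ratio(ct_c, ct_t, [rc], [rt])

        pool_t = np.concatenate([ct_c, ct_t])
        pool_r = np.concatenate([rc, rt])

        def ratio_for(ctrl_idx):
            mask = np.zeros(6, dtype=bool)
            mask[list(ctrl_idx)] = True
            d_t = pool_t[mask].mean() - pool_t[~mask].mean()
            d_r = pool_r[mask].mean() - pool_r[~mask].mean()
            return 2.0 ** d_t / 2.0 ** d_r

        obs = max(res.ratio, 1 / res.ratio)
        count = 0
        for ctrl in combinations(range(6), 3):
            r = ratio_for(ctrl)
            if max(r, 1 / r) >= obs - 1e-12:
                count += 1
        assert res.p_random == pytest.approx(count / 20)
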