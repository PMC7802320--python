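"""2x2 association statistics: exact-test oracles, OR laws, FDR, cohort tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dsvpipe as dp


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by brute-force hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[0, 5], [5, 0]], 2 / 252),
            ([[2, 0], [0, 2]], 1 / 3),
        ],
    )
    def test_hand_enumerated_examples(self, table, expected):
        assert dp.fisher_exact_two_sided(table) == pytest.approx(expected, rel=1e-9)

    def test_family_history_row_is_nonsignificant(self):
        # observed cell sits at the hypergeometric mode -> p at the ceiling
        assert dp.fisher_exact_two_sided([[11, 32], [14, 42]]) >= 0.99

    def test_empty_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="margin"):
            assert dp.fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0

    def test_exhaustive_agreement_with_enumeration_small_n(self):
        """Minimum-likelihood rule vs full enumeration, all tables N <= 16."""
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if 0 in np.array(t).sum(0) or 0 in np.array(t).sum(1):
                            continue
                        assert dp.fisher_exact_two_sided(t) == pytest.approx(
                            fisher_enumeration_oracle(a, b, c, d), rel=1e-9, abs=1e-12
                        )

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(0, 60),
        st.integers(0, 60),
        st.integers(0, 60),
        st.integers(0, 60),
    )
    def test_sampled_agreement_with_enumeration_up_to_60(self, a, b, c, d):
        if a + b + c + d == 0 or a + b + c + d > 60:
            return
        t = np.array([[a, b], [c, d]])
        if 0 in t.sum(0) or 0 in t.sum(1):
            return
        assert dp.fisher_exact_two_sided(t) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestYatesChiSquare:
    @pytest.mark.parametrize(
        "table,p_expected",
        [
            ([[12, 25], [13, 48]], 0.3245),  # KRAS mutated vs recurrence
            ([[2, 10], [23, 64]], 0.707),    # mucinous histology
        ],
    )
    def test_characteristic_rows(self, table, p_expected):
        _, p = dp.yates_chi_square(table)
        assert p == pytest.approx(p_expected, abs=5e-4)

    def test_continuity_clamp_gives_zero_statistic(self):
        stat, p = dp.yates_chi_square([[11, 32], [14, 42]])
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(1, 40, size=(2, 2))
            stat, p = dp.yates_chi_square(t)
            s2, p2, _, _ = stats.chi2_contingency(t, correction=True)
            assert stat == pytest.approx(s2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dp.yates_chi_square([[0, 0], [3, 4]])


class TestOddsRatio:
    def test_symmetric_table(self):
        res = dp.odds_ratio_ci([[5, 5], [5, 5]])
        assert res.odds_ratio == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_family_history_counts_give_1_375(self):
        res = dp.odds_ratio_ci([[91, 177], [86, 230]])
        assert res.odds_ratio == pytest.approx(20930 / 15222, rel=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 80)] * 4))
    def test_transformation_laws(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]])
        base = dp.odds_ratio_ci(t).odds_ratio
        assert dp.odds_ratio_ci(t.T).odds_ratio == pytest.approx(base, rel=1e-12)
        swapped = dp.odds_ratio_ci(t[::-1]).odds_ratio
        assert swapped == pytest.approx(1 / base, rel=1e-12)

    def test_zero_cell_triggers_haldane(self):
        res = dp.odds_ratio_ci([[0, 5], [5, 5]])
        assert res.corrected and res.odds_ratio > 0

    def test_cross_zero_pattern_undefined(self):
        with pytest.raises(ValueError, match="cross"):
            dp.odds_ratio_ci([[0, 5], [5, 0]])


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            dp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_and_single_p_unchanged(self):
        np.testing.assert_allclose(dp.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(dp.bh_adjust([0.73]), [0.73])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_above_raw(self, ps):
        adj = dp.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1 + 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.bh_adjust([0.5, 1.5])


class TestGeneSpectrum:
    def test_planted_risk_gene_ranks_top(self, planted_risk_sim):
        _, records, cohort, carriers, truth = planted_risk_sim
        gene_map = dp.annotate_genes(records, dp.simulate.gene_models_for(records))
        spectrum = dp.dsv_gene_spectrum(carriers, cohort, gene_map)
        top = dp.top_k_by_direction(spectrum, k=10)["risk"]
        planted_genes = {f"GENE_{d}" for d in truth.risk_dsv_ids}
        assert len(set(top["unit"]) & planted_genes) >= 8
        sig = spectrum[spectrum["p_adj"] < 0.05]
        assert set(sig["unit"]) & planted_genes  # planted genes reach FDR significance

    def test_sample_permutation_invariance(self, planted_risk_sim):
        _, records, cohort, carriers, _ = planted_risk_sim
        gene_map = dp.annotate_genes(records, dp.simulate.gene_models_for(records))
        s1 = dp.dsv_gene_spectrum(carriers, cohort, gene_map)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort))
        s2 = dp.dsv_gene_spectrum(carriers, cohort.iloc[perm], gene_map)
        pd.testing.assert_frame_equal(s1, s2)

    def test_universal_carrier_gene_skipped(self):
        data = pd.DataFrame(
            {"D0": [1, 1, 1, 1], "D1": [0, 1, 0, 1]},
            index=[f"S{i}" for i in range(4)],
        ).astype(np.int8)
        cm = dp.CarrierMatrix(
            data=data,
            metadata=pd.DataFrame(
                {"dsv_id": ["D0", "D1"], "chromosome": "chr1", "start": [1, 1], "end": [600, 600]}
            ),
        )
        cohort = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(4)],
                "cohort_label": ["cancer", "cancer", "non-cancer", "non-cancer"],
            }
        )
        spec = dp.dsv_gene_spectrum(cm, cohort, {"D0": ["GA"], "D1": ["GB"]})
        assert list(spec["unit"]) == ["GB"]


class TestFchAnalysis:
    def _cohort(self, seed=0, n=300, or_=2.0):
        cfg = dp.SimulationConfig(
            n_cancer=n, n_control=n, m_background=1, fch_odds_ratio=or_, seed=seed
        )
        _, cohort, _ = dp.simulate_genotypes(cfg)
        return cohort

    def test_printed_counts_reproduced(self):
        cohort = pd.DataFrame(
            {
                "sample_id": [str(i) for i in range(584)],
                "cohort_label": ["cancer"] * 177 + ["non-cancer"] * 407,
                "fch": ["yes"] * 91 + ["no"] * 86 + ["yes"] * 177 + ["no"] * 230,
            }
        )
        res = dp.fch_analysis(cohort)
        assert res.odds_ratio == pytest.approx(1.375, abs=5e-4)
        np.testing.assert_array_equal(res.table, [[91, 177], [86, 230]])

    def test_ci_coverage_of_planted_or(self):
        covered = 0
        for rep in range(100):
            res = dp.fch_analysis(self._cohort(seed=rep))
            covered += res.ci_low <= 2.0 <= res.ci_high
        assert covered >= 88  # ~95% nominal coverage

    def test_unknown_fch_excluded_and_counted(self):
        cohort = self._cohort()
        cohort.loc[:9, "fch"] = "unknown"
        assert dp.fch_analysis(cohort).n_unknown == 10

    def test_all_unknown_rejected(self):
        cohort = self._cohort()
        cohort["fch"] = "unknown"
        with pytest.raises(ValueError):
            dp.fch_analysis(cohort)


class TestFchStratified:
    def test_planted_fch_linked_dsv_detected(self):
        """A deletion enriched in FCH-positive patients is flagged within the
        cancer stratum at p < 0.05 in most replicates (OR=4, n=300)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            n = 300
            fch = rng.binomial(1, 0.45, n)
            p_carrier = np.where(fch == 1, 0.45, 4 * 0.45 / (1 + 3 * 0.45) / (1 + 4 * 0.45 / (1 + 3 * 0.45)))
            # carrier odds = OR * odds(base): base 0.2 for fch=no
            odds = 4 * 0.2 / 0.8
            p_carrier = np.where(fch == 1, odds / (1 + odds), 0.2)
            x = rng.binomial(1, p_carrier)
            data = pd.DataFrame({"D0": x}, index=[f"S{i}" for i in range(n)]).astype(np.int8)
            cm = dp.CarrierMatrix(
                data=data,
                metadata=pd.DataFrame(
                    {"dsv_id": ["D0"], "chromosome": "chr1", "start": [1], "end": [600]}
                ),
            )
            cohort = pd.DataFrame(
                {
                    "sample_id": data.index,
                    "cohort_label": "cancer",
                    "fch": np.where(fch == 1, "yes", "no"),
                }
            )
            cohort.loc[len(cohort)] = ["X0", "non-cancer", "yes"]
            res = dp.fch_stratified_dsv_tests(cm, cohort, min_stratum=5)
            if "cancer" in res and len(res["cancer"]) and res["cancer"]["p"].iloc[0] < 0.05:
                hits += 1
        assert hits >= 16  # >= 80% power

    def test_small_stratum_skipped_with_warning(self, planted_risk_sim):
        _, _, cohort, carriers, _ = planted_risk_sim
        cohort = cohort.copy()
        cohort.loc[cohort["cohort_label"] == "non-cancer", "fch"] = "no"
        with pytest.warns(UserWarning, match="stratum"):
            res = dp.fch_stratified_dsv_tests(carriers, cohort)
        assert "non-cancer" not in res


class TestCharacteristicsTable:
    def _crc_cohort(self):
        rows = []
        # KRAS: mutated 12/25, wild 13/48 -> recurrence/non-recurrence
        spec = [("mutated", "yes", 12), ("mutated", "no", 25), ("wild", "yes", 13), ("wild", "no", 48)]
        for level, rec, k in spec:
            for _ in range(k):
                rows.append({"kras": level, "recurrence": rec})
        df = pd.DataFrame(rows)
        # mucinous: 2/10 vs 23/64
        muc = ["mucinous"] * 2 + ["nonmucinous"] * 23 + ["mucinous"] * 10 + ["nonmucinous"] * 64
        rec = ["yes"] * 25 + ["no"] * 74
        df2 = pd.DataFrame({"histology": muc, "recurrence": rec})
        # FCH 11/32 vs 14/42
        fch = ["yes"] * 11 + ["no"] * 14 + ["yes"] * 32 + ["no"] * 42
        df3 = pd.DataFrame({"fch_flag": fch, "recurrence": ["yes"] * 25 + ["no"] * 74})
        return df, df2, df3

    def test_printed_p_values_recomputed(self):
        kras, muc, fch = self._crc_cohort()
        p_kras = dp.characteristics_table(kras, ["kras"]).iloc[0]
        assert p_kras["p"] == pytest.approx(0.3245, abs=5e-4)
        assert p_kras["test"] == "yates-chi-square"
        p_muc = dp.characteristics_table(muc, ["histology"]).iloc[0]
        assert p_muc["p"] == pytest.approx(0.707, abs=5e-4)
        p_fch = dp.characteristics_table(fch, ["fch_flag"]).iloc[0]
        assert p_fch["p"] > 0.99

    def test_sparse_table_uses_fisher(self):
        # one deficient sample among 99: expected count < 1 -> exact test
        df = pd.DataFrame(
            {
                "mmr": ["deficient"] + ["proficient"] * 98,
                "recurrence": ["yes"] * 25 + ["no"] * 74,
            }
        )
        row = dp.characteristics_table(df, ["mmr"]).iloc[0]
        assert row["test"] == "fisher-exact"

    def test_single_level_covariate_has_no_p(self):
        df = pd.DataFrame({"site": ["left"] * 20, "recurrence": ["yes"] * 5 + ["no"] * 15})
        row = dp.characteristics_table(df, ["site"]).iloc[0]
        assert np.isnan(row["p"])
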