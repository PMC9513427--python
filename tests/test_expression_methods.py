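"""Tests for the three quantification routes and their cross-method identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrkit import (
    CurveFit,
    GeneSpec,
    SimulationConfig,
    ddct_admissibility,
    expr_by_curve,
    expr_ddct,
    expr_rqpcr,
    fit_curve,
    quantity_from_curve,
    simulate_cq_experiment,
    stability_rank,
    true_fold_change,
)
from qpcrkit._util import PairingError, geometric_mean
from qpcrkit.expr_curve import ExtrapolationWarning

DOUBLING_SLOPE = -1 / math.log10(2)


def doubling_fit(gene="g", intercept=25.0, cq_range=(10.0, 35.0)):
    eff = 100.0
    return CurveFit(gene=gene, slope=DOUBLING_SLOPE, intercept=intercept,
                    r_squared=1.0, efficiency_pct=eff, amp_factor=2.0,
                    n_points=6, cq_range=cq_range)


class TestQuantityFromCurve:
    def test_intercept_maps_to_unit_quantity(self):
        assert quantity_from_curve(25.0, doubling_fit()) == pytest.approx(1.0)

    def test_one_dilution_step_down(self):
        fit = doubling_fit()
        q = quantity_from_curve(25.0 - DOUBLING_SLOPE, fit)  # cq = 28.32193
        assert q == pytest.approx(0.1, rel=1e-9)

    def test_extrapolation_warns_then_forbids(self):
        fit = doubling_fit(cq_range=(20.0, 30.0))
        with pytest.warns(ExtrapolationWarning):
            quantity_from_curve(35.0, fit)
        with pytest.raises(ValueError, match="outside"):
            quantity_from_curve(35.0, fit, extrapolation="forbid")

    def test_invalid_fit_rejected(self):
        bad = CurveFit("g", 0.5, 20.0, 0.9, float("nan"), float("nan"), 4, (10, 30))
        with pytest.raises(ValueError, match="invalid"):
            quantity_from_curve(24.0, bad)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(slope=st.floats(-4.5, -2.5), intercept=st.floats(15, 30),
           cq=st.floats(12, 34))
    def test_round_trip_through_the_line(self, slope, intercept, cq):
        amp = 10 ** (-1 / slope)
        fit = CurveFit("g", slope, intercept, 1.0, (amp - 1) * 100, amp, 4, (10.0, 36.0))
        q = quantity_from_curve(cq, fit)
        assert slope * math.log10(q) + intercept == pytest.approx(cq, abs=1e-10)


class TestExprByCurve:
    def fits_for(self, cq_table, intercepts=(30.0, 30.0)):
        return {"target": doubling_fit("target", intercepts[0]),
                "ref": doubling_fit("ref", intercepts[1])}

    def test_self_normalization_symmetry(self, small_cq_table):
        """A target whose Cq pattern and curve match the reference exactly is 1.0."""
        tab = small_cq_table.copy()
        clone = tab[tab["gene"] == "ref"].assign(gene="ref_clone")
        tab = pd.concat([tab, clone], ignore_index=True)
        fits = {g: doubling_fit(g) for g in ("target", "ref", "ref_clone")}
        res = expr_by_curve(tab, fits, "ref")
        clone_vals = res.loc[res["gene"] == "ref_clone", "rel_expr"]
        assert np.allclose(clone_vals, 1.0, atol=1e-12)

    def test_two_cycle_shift_gives_fourfold(self, small_cq_table):
        res = expr_by_curve(small_cq_table, self.fits_for(small_cq_table), "ref")
        by_group = res.groupby("group")["rel_expr"].mean()
        assert by_group["treatment"] / by_group["control"] == pytest.approx(4.0, rel=1e-9)

    def test_reference_excluded_from_output(self, small_cq_table):
        res = expr_by_curve(small_cq_table, self.fits_for(small_cq_table), "ref")
        assert "ref" not in set(res["gene"])

    def test_missing_reference_well_errors(self, small_cq_table):
        broken = small_cq_table[~((small_cq_table["gene"] == "ref") &
                                  (small_cq_table["group"] == "treatment") &
                                  (small_cq_table["bio_rep"] == 2))]
        with pytest.raises(PairingError, match="treatment"):
            expr_by_curve(broken, self.fits_for(broken), "ref")

    def test_missing_fit_errors(self, small_cq_table):
        with pytest.raises(ValueError, match="target"):
            expr_by_curve(small_cq_table, {"ref": doubling_fit("ref")}, "ref")

    def test_monotone_decreasing_in_target_cq(self):
        fit = doubling_fit()
        qs = [quantity_from_curve(cq, fit) for cq in np.linspace(18, 30, 10)]
        assert all(a > b for a, b in zip(qs, qs[1:]))


class TestExprDdct:
    def test_null_case_all_unity(self):
        cfg = SimulationConfig(seed=0, fold_changes={"c": {}, "t": {}}, cq_noise_sd=0.0)
        res = expr_ddct(simulate_cq_experiment(cfg), "ref", "c")
        assert np.allclose(res["fold_change"], 1.0, atol=1e-12)
        assert np.allclose(res["delta_delta_ct"], 0.0, atol=1e-12)

    def test_closed_form_two_cycle_difference(self, small_cq_table):
        res = expr_ddct(small_cq_table, "ref", "control")
        trt = res[res["group"] == "treatment"]
        assert np.allclose(trt["fold_change"], 4.0, rtol=1e-9)

    def test_matches_spreadsheet_oracle_on_noisy_fixture(self):
        """Explicit per-cell arithmetic on a 2-gene x 2-group x 3-rep table."""
        rng = np.random.default_rng(5)
        rows = []
        cq = {}
        for gene in ("t1", "hk"):
            for grp in ("c", "trt"):
                for rep in (1, 2, 3):
                    val = rng.uniform(18, 28)
                    cq[(gene, grp, rep)] = val
                    rows.append({"gene": gene, "group": grp, "bio_rep": rep,
                                 "tech_rep": 1, "cq": val})
        res = expr_ddct(pd.DataFrame(rows), "hk", "c").set_index(["group", "bio_rep"])
        dct = {(g, r): cq[("t1", g, r)] - cq[("hk", g, r)]
               for g in ("c", "trt") for r in (1, 2, 3)}
        ctrl_mean = sum(dct[("c", r)] for r in (1, 2, 3)) / 3
        for g in ("c", "trt"):
            for r in (1, 2, 3):
                expected = 2 ** -(dct[(g, r)] - ctrl_mean)
                assert res.loc[(g, r), "fold_change"] == pytest.approx(expected, rel=1e-12)

    def test_control_centering_zero_mean(self, noisy_cq_table):
        res = expr_ddct(noisy_cq_table, "ref", "control")
        ctrl = res[res["group"] == "control"]
        assert abs(ctrl["delta_delta_ct"].mean()) < 1e-12
        # Ct-scale centering => geometric mean of control fold changes is 1
        assert geometric_mean(ctrl["fold_change"]) == pytest.approx(1.0, abs=1e-12)

    def test_global_cq_shift_invariance(self, noisy_cq_table):
        res = expr_ddct(noisy_cq_table, "ref", "control")
        shifted = noisy_cq_table.assign(cq=noisy_cq_table["cq"] + 3.7)
        res2 = expr_ddct(shifted, "ref", "control")
        assert np.allclose(res["fold_change"], res2["fold_change"], atol=1e-12)

    def test_missing_control_group_errors(self, small_cq_table):
        with pytest.raises(ValueError, match="nosuch"):
            expr_ddct(small_cq_table, "ref", "nosuch")

    def test_unpaired_target_errors(self, small_cq_table):
        broken = small_cq_table[~((small_cq_table["gene"] == "ref") &
                                  (small_cq_table["bio_rep"] == 1) &
                                  (small_cq_table["group"] == "control"))]
        with pytest.raises(PairingError):
            expr_ddct(broken, "ref", "control")


class TestDdctAdmissibility:
    def make_fits(self, eff_by_gene):
        out = {}
        for g, eff in eff_by_gene.items():
            amp = 1 + eff / 100
            out[g] = CurveFit(g, -1 / math.log10(amp), 25.0, 1.0, eff, amp, 4, (15, 32))
        return out

    def test_threshold_classification(self):
        fits = self.make_fits({"ok": 98.0, "bad": 85.0, "hk": 102.0})
        rep = ddct_admissibility(fits, "hk", tolerance_pct=5.0).set_index("gene")
        assert bool(rep.loc["ok", "admissible"])
        assert not bool(rep.loc["bad", "admissible"])

    def test_empty_fits_vacuous(self):
        assert ddct_admissibility({}, "hk").empty


class TestExprRqpcr:
    EFFS = {"target": 2.0, "ref": 2.0}

    def test_identity_with_ddct_single_reference(self, noisy_cq_table):
        """With one reference and perfect doubling, NRQ scaling reduces
        exactly to the 2^-ddCt fold change."""
        ddct = expr_ddct(noisy_cq_table, "ref", "control")
        rq = expr_rqpcr(noisy_cq_table, ["ref"], self.EFFS, "control")
        merged = ddct.merge(rq, on=["gene", "group", "bio_rep"])
        assert (merged["fold_change"] - merged["nrq_scaled"]).abs().max() < 1e-9

    def test_geometric_mean_normalization_factor(self):
        # two references engineered so RQ = 4 and 1 in the same sample
        rows = []
        base = {"r1": 20.0, "r2": 24.0, "t": 22.0}
        for gene, b in base.items():
            for i, grp in enumerate(["c", "trt"]):
                shift = {"r1": [1.0, -1.0], "r2": [0.0, 0.0], "t": [0.0, 0.0]}[gene][i]
                for rep in (1, 2):
                    rows.append({"gene": gene, "group": grp, "bio_rep": rep,
                                 "tech_rep": 1, "cq": b + shift})
        res = expr_rqpcr(pd.DataFrame(rows), ["r1", "r2"],
                         {"r1": 2.0, "r2": 2.0, "t": 2.0}, "c")
        # r1 RQ in group c: 2^(mean-cq) = 2^-1 = 0.5; in trt: 2.  r2 RQ = 1.
        nf = res.set_index(["group", "bio_rep"])["nf"]
        assert nf.loc[("trt", 1)] == pytest.approx(math.sqrt(2.0), rel=1e-12)
        assert nf.loc[("c", 1)] == pytest.approx(math.sqrt(0.5), rel=1e-12)

    def test_null_case_everything_unity(self):
        rows = [{"gene": g, "group": grp, "bio_rep": r, "tech_rep": 1, "cq": 24.0}
                for g in ("a", "b", "hk") for grp in ("c", "t") for r in (1, 2)]
        res = expr_rqpcr(pd.DataFrame(rows), ["hk"], {"a": 2, "b": 2, "hk": 2}, "c")
        for col in ("rq", "nf", "nrq", "nrq_scaled"):
            assert np.allclose(res[col], 1.0, atol=1e-12)

    def test_reference_permutation_invariance(self, noisy_cq_table):
        tab = pd.concat([
            noisy_cq_table,
            noisy_cq_table[noisy_cq_table["gene"] == "ref"].assign(
                gene="ref2", cq=lambda d: d["cq"] + 1.3),
        ], ignore_index=True)
        effs = {"target": 2.0, "ref": 2.0, "ref2": 2.0}
        a = expr_rqpcr(tab, ["ref", "ref2"], effs, "control")
        b = expr_rqpcr(tab, ["ref2", "ref"], effs, "control")
        assert np.allclose(a["nf"], b["nf"], atol=0)
        assert np.allclose(a["nrq_scaled"], b["nrq_scaled"], atol=0)

    def test_reference_shift_invariance(self, noisy_cq_table):
        res = expr_rqpcr(noisy_cq_table, ["ref"], self.EFFS, "control")
        shifted = noisy_cq_table.copy()
        mask = shifted["gene"] == "ref"
        shifted.loc[mask, "cq"] += 2.5
        res2 = expr_rqpcr(shifted, ["ref"], self.EFFS, "control")
        assert np.allclose(res["nrq"], res2["nrq"], atol=1e-10)

    def test_control_geometric_mean_is_one(self, noisy_cq_table):
        res = expr_rqpcr(noisy_cq_table, ["ref"], self.EFFS, "control")
        ctrl = res[res["group"] == "control"]
        assert geometric_mean(ctrl["nrq_scaled"]) == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_gap_shifts_estimate_directionally(self, small_cq_table):
        """When the true chemistry amplifies slower than 2x, a given fold
        change costs more cycles, so assuming base 2 overstates it; the
        corrected method recovers the truth."""
        cfg = SimulationConfig(
            seed=2,
            genes={"target": GeneSpec(1.85, 24.0), "ref": GeneSpec(1.95, 20.0)},
            fold_changes={"control": {"target": 1.0}, "treatment": {"target": 4.0}},
            n_bio=4, n_tech=2, cq_noise_sd=0.0,
        )
        tab = simulate_cq_experiment(cfg)
        corrected = expr_rqpcr(tab, ["ref"], {"target": 1.85, "ref": 1.95}, "control")
        naive = expr_ddct(tab, "ref", "control")
        est_corr = corrected[corrected["group"] == "treatment"]["nrq_scaled"].mean()
        est_naive = naive[naive["group"] == "treatment"]["fold_change"].mean()
        assert est_corr == pytest.approx(4.0, rel=1e-9)
        assert est_naive > est_corr  # base-2 on a >2.25-cycle shift inflates the fold

    def test_amp_factor_below_one_rejected(self, small_cq_table):
        with pytest.raises(ValueError, match="amplification factor"):
            expr_rqpcr(small_cq_table, ["ref"], {"target": 0.9, "ref": 2.0}, "control")

    def test_sample_missing_reference_errors(self, small_cq_table):
        broken = small_cq_table[~((small_cq_table["gene"] == "ref") &
                                  (small_cq_table["bio_rep"] == 3) &
                                  (small_cq_table["group"] == "treatment"))]
        with pytest.raises(PairingError, match="ref"):
            expr_rqpcr(broken, ["ref"], self.EFFS, "control")


class TestStabilityRank:
    def test_constant_candidate_ranks_first(self):
        rows = []
        for grp in ("c", "t"):
            for rep in (1, 2, 3):
                rows.append({"gene": "flat", "group": grp, "bio_rep": rep,
                             "tech_rep": 1, "cq": 20.0})
                rows.append({"gene": "wobbly", "group": grp, "bio_rep": rep,
                             "tech_rep": 1, "cq": 20.0 + (-1) ** rep})
        rank = stability_rank(pd.DataFrame(rows), ["wobbly", "flat"],
                              {"flat": 2.0, "wobbly": 2.0})
        assert rank.loc[0, "gene"] == "flat"
        assert rank.loc[0, "sd_log2_rq"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_sd(self, noisy_cq_table):
        tab = pd.concat([
            noisy_cq_table,
            noisy_cq_table[noisy_cq_table["gene"] == "ref"].assign(gene="r2"),
        ], ignore_index=True)
        effs = {"target": 2.0, "ref": 2.0, "r2": 2.0}
        rank = stability_rank(tab, ["target", "ref", "r2"], effs).set_index("gene")
        agg = tab.groupby(["gene", "group", "bio_rep"])["cq"].mean().reset_index()
        for gene in ("target", "ref", "r2"):
            cqs = agg[agg["gene"] == gene]["cq"].to_numpy()
            log2rq = (cqs.mean() - cqs) * 1.0  # A=2: log2(RQ) = mean - cq
            assert rank.loc[gene, "sd_log2_rq"] == pytest.approx(
                np.std(log2rq, ddof=1), rel=1e-12)

    def test_single_candidate_rejected(self, small_cq_table):
        with pytest.raises(ValueError, match="2"):
            stability_rank(small_cq_table, ["ref"], {"ref": 2.0})


class TestCrossMethodAgreement:
    def test_curve_method_agrees_with_ddct_at_perfect_doubling(self, noisy_cq_table):
        fits = {g: doubling_fit(g, intercept=28.0) for g in ("target", "ref")}
        by_curve = expr_by_curve(noisy_cq_table, fits, "ref")
        by_ddct = expr_ddct(noisy_cq_table, "ref", "control")
        fc_curve = (by_curve[by_curve["group"] == "treatment"]["rel_expr"].mean()
                    / by_curve[by_curve["group"] == "control"]["rel_expr"].mean())
        m = by_ddct.groupby("group")["fold_change"].mean()
        fc_ddct = m["treatment"] / m["control"]
        assert fc_curve == pytest.approx(fc_ddct, rel=1e-9)

    def test_parameter_recovery_with_unequal_efficiencies(self):
        """Gene-specific amplification factors {1.85, 2.0, 1.95}: the
        efficiency-corrected route recovers the true fold change while the
        fixed-base-2 route is biased."""
        effs = {"t1": 1.85, "t2": 2.0, "ref": 1.95}
        corr_est, naive_est = [], []
        for seed in range(120):
            cfg = SimulationConfig(
                seed=seed,
                genes={g: GeneSpec(a, 24.0) for g, a in effs.items()},
                fold_changes={"control": {}, "treatment": {"t1": 4.0, "t2": 4.0}},
                n_bio=6, n_tech=2, cq_noise_sd=0.15,
            )
            tab = simulate_cq_experiment(cfg)
            rq = expr_rqpcr(tab, ["ref"], effs, "control")
            dd = expr_ddct(tab, "ref", "control")
            corr_est.append(rq[(rq["gene"] == "t1") &
                               (rq["group"] == "treatment")]["nrq_scaled"].mean())
            naive_est.append(dd[(dd["gene"] == "t1") &
                                (dd["group"] == "treatment")]["fold_change"].mean())
        assert np.mean(corr_est) == pytest.approx(4.0, rel=0.10)
        assert abs(np.mean(naive_est) - 4.0) > abs(np.mean(corr_est) - 4.0)
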