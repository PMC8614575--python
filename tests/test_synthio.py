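import numpy as np
import pandas as pd
import pytest

from rumeth import community, gaskin, ranking, synthio
from rumeth.errors import InvalidParameterError


class TestDeterminism:
    def test_herd(self):
        a = synthio.gen_herd(synthio.HerdTruth(seed=42))
        b = synthio.gen_herd(synthio.HerdTruth(seed=42))
        pd.testing.assert_frame_equal(a.cows, b.cows)
        pd.testing.assert_series_equal(a.offsets, b.offsets)

    def test_invitro(self):
        truth = synthio.default_invitro_truth(seed=42)
        design = synthio.TreatmentDesign(runs=(1,))
        a = synthio.gen_invitro_run(truth, design)
        b = synthio.gen_invitro_run(truth, design)
        for ca, cb in zip(a.gas_curves, b.gas_curves):
            assert ca.bottle_id == cb.bottle_id
            assert np.array_equal(ca.volume, cb.volume)
        for sa, sb in zip(a.headspace_series, b.headspace_series):
            assert np.array_equal(sa.ch4_fraction, sb.ch4_fraction)
        for pa, pb in zip(a.vfa_profiles, b.vfa_profiles):
            assert np.array_equal(pa.values(), pb.values())

    def test_otu_table(self):
        a = synthio.gen_otu_table(synthio.default_community_truth(seed=42))
        b = synthio.gen_otu_table(synthio.default_community_truth(seed=42))
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestHerd:
    def test_noise_free_is_exact_linear_predictor(self):
        truth = synthio.HerdTruth(animal_offset_sd=0.0, residual_sd=0.0, seed=9)
        sim = synthio.gen_herd(truth)
        pred = (truth.intercept + truth.beta_dmi * sim.cows["dmi"]
                + truth.beta_bw * sim.cows["bw"]
                + sim.cows["period"].map({"P1": -5.0, "P2": 5.0}))
        assert np.allclose(sim.cows["ch4_obs"], pred)
        fit = ranking.fit_ch4_model(sim.cows)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_default_group_means_match_table_scale(self):
        # selected low/high group means near 331 and 442 g/d over 200 herds
        lows, highs = [], []
        for seed in range(200):
            sim = synthio.gen_herd(synthio.HerdTruth(seed=seed))
            rk = ranking.rank_emitters(ranking.fit_ch4_model(sim.cows), 7)
            tab = rk.table.set_index("cow_id")
            obs = sim.cows.groupby("cow_id")["ch4_obs"].mean()
            lows.append(obs.loc[tab.index[tab["group"] == "low"]].mean())
            highs.append(obs.loc[tab.index[tab["group"] == "high"]].mean())
        for vals, target in ((lows, 331.0), (highs, 442.0)):
            sem = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - target) <= 3 * sem

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            synthio.HerdTruth(n_cows=1)
        with pytest.raises(InvalidParameterError):
            synthio.HerdTruth(animal_offset_sd=-1.0)


class TestInVitro:
    def test_noise_free_curve_equals_truth(self, noisefree_invitro_run):
        run = noisefree_invitro_run
        truth = run.truth
        blanks = [c for c in run.gas_curves if c.meta["is_blank"]]
        for c in run.gas_curves:
            if c.meta["is_blank"]:
                continue
            net = gaskin.blank_correct_gas(c, blanks)
            expected = truth.gas_kinetics[(c.meta["diet"], c.meta["cnsl"])].evaluate(c.time)
            assert np.allclose(net.volume, expected, atol=1e-9)

    def test_noise_free_gompertz_recovery_1e6(self, noisefree_invitro_run):
        run = noisefree_invitro_run
        truth = run.truth
        blanks = [c for c in run.gas_curves if c.meta["is_blank"]]
        c = next(c for c in run.gas_curves
                 if not c.meta["is_blank"] and c.meta["diet"] == "S"
                 and c.meta["cnsl"] == "without")
        net = gaskin.blank_correct_gas(c, blanks)
        fit = gaskin.fit_two_pool_gompertz(net.time, net.volume / net.sample_mass)
        tk = truth.gas_kinetics[("S", "without")]
        true_params = np.array([tk.a1, tk.b1, tk.k1, tk.a2, tk.b2, tk.k2])
        rel = np.abs(np.array(fit.params) - true_params) / true_params
        assert rel.max() <= 1e-6

    def test_cnsl_ch4_asymptote_ratio(self, noisefree_invitro_run):
        # CNSL truths have CH4 asymptote ~15 vs ~36 without; the fitted
        # ratio survives the log-concentration approximation
        run = noisefree_invitro_run
        blanks = [c for c in run.gas_curves if c.meta["is_blank"]]
        hs = {s.bottle_id: s for s in run.headspace_series}
        fitted = {}
        for c in run.gas_curves:
            if c.meta["is_blank"] or c.meta["replicate"] != 1:
                continue
            net = gaskin.blank_correct_gas(c, blanks)
            conc = gaskin.fit_log_conc(hs[c.bottle_id])
            ch4 = gaskin.estimate_ch4_curve(net, conc, run.truth.headspace_volume)
            fit = gaskin.fit_two_pool_gompertz(ch4.time, ch4.cumulative)
            fitted[(c.meta["diet"], c.meta["cnsl"])] = fit.asymptote
        with_mean = np.mean([fitted[("S", "with")], fitted[("SB", "with")]])
        without_mean = np.mean([fitted[("S", "without")], fitted[("SB", "without")]])
        assert with_mean / without_mean == pytest.approx(0.41, abs=0.08)

    def test_blank_only_design_nets_to_zero(self):
        zero = synthio.PoolTruth(0.0, 2.0, 0.1, 0.0, 2.0, 0.05)
        truth = synthio.default_invitro_truth(
            gas_noise_sd=0.0, conc_noise_sd=0.0,
            gas_kinetics={(d, c): zero for d in ("S", "SB")
                          for c in ("without", "with")},
            ch4_kinetics={(d, c): zero for d in ("S", "SB")
                          for c in ("without", "with")},
            seed=1)
        run = synthio.gen_invitro_run(truth, synthio.TreatmentDesign(runs=(1,)))
        blanks = [c for c in run.gas_curves if c.meta["is_blank"]]
        blank_mean = np.mean([b.volume for b in blanks], axis=0)
        for c in run.gas_curves:
            if c.meta["is_blank"]:
                continue
            assert np.allclose(c.volume, blank_mean, atol=1e-9)
            net = gaskin.blank_correct_gas(c, blanks)
            assert np.allclose(net.volume, 0.0, atol=1e-9)

    def test_vfa_proportions_sum_to_1000(self):
        truth = synthio.default_invitro_truth(vfa_noise_sd=0.05, seed=2)
        run = synthio.gen_invitro_run(truth, synthio.TreatmentDesign(runs=(1,)))
        for p in run.vfa_profiles:
            assert p.values().sum() == pytest.approx(1000.0, abs=1e-9)

    def test_bad_grid_rejected(self):
        truth = synthio.default_invitro_truth(horizon=48.1, seed=0)
        with pytest.raises(InvalidParameterError):
            synthio.gen_invitro_run(truth, synthio.TreatmentDesign(runs=(1,)))

    def test_counts_contract(self):
        with pytest.raises(InvalidParameterError):
            synthio.default_invitro_truth(n_replicates=0)


class TestOtuGeneration:
    def test_default_bacteroidetes_mean(self):
        means = []
        for seed in range(100):
            table = synthio.gen_otu_table(synthio.default_community_truth(seed=seed))
            means.append(community.relative_abundance(table, "phylum")
                         ["Bacteroidetes"].mean())
        sem = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.625) <= 3 * sem

    def test_archaeal_clade_means(self):
        ro, sgmt = [], []
        for seed in range(100):
            table = synthio.gen_otu_table(synthio.default_community_truth(seed=seed))
            arch = community.archaeal_profile(table)
            ro.append(arch["RO"].mean())
            sgmt.append(arch["SGMT"].mean())
        for vals, target in ((ro, 0.215), (sgmt, 0.698)):
            sem = np.std(vals) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - target) <= 3 * sem

    def test_multinomial_limit_variance(self):
        # overdispersion -> inf: per-taxon proportion sd matches the
        # multinomial closed form sqrt(p(1-p)/N)
        truth = synthio.default_community_truth(
            overdispersion=np.inf, library_sd=0.0, n_per_group=100, seed=5)
        table = synthio.gen_otu_table(truth)
        props = table.counts.div(table.counts.sum(axis=1), axis=0)
        comp = dict(zip(truth.taxa, truth.composition))
        for otu in ("otu_prev1", "otu_rf16", "otu_lachno"):
            p = comp[otu]
            expected_sd = np.sqrt(p * (1 - p) / truth.library_mean)
            assert props[otu].std(ddof=1) == pytest.approx(expected_sd, rel=0.2)

    def test_overdispersed_variance_larger(self):
        base = dict(library_sd=0.0, n_per_group=100, seed=5)
        t_inf = synthio.default_community_truth(overdispersion=np.inf, **base)
        t_fin = synthio.default_community_truth(overdispersion=110.0, **base)
        sd_inf = synthio.gen_otu_table(t_inf).counts.pipe(
            lambda c: c.div(c.sum(axis=1), axis=0))["otu_prev1"].std()
        sd_fin = synthio.gen_otu_table(t_fin).counts.pipe(
            lambda c: c.div(c.sum(axis=1), axis=0))["otu_prev1"].std()
        assert sd_fin > 3 * sd_inf

    def test_group_effect_shifts_composition(self):
        effect = np.ones(len(synthio.default_community_truth().taxa))
        effect[0] = 4.0
        truth = synthio.default_community_truth(group_effect=tuple(effect),
                                                n_per_group=50, seed=3)
        table = synthio.gen_otu_table(truth)
        props = table.counts.div(table.counts.sum(axis=1), axis=0)
        otu = truth.taxa[0]
        high = props.loc[table.metadata["emitter"] == "high", otu].mean()
        low = props.loc[table.metadata["emitter"] == "low", otu].mean()
        assert high > 2 * low

    def test_bad_composition_rejected(self):
        truth = synthio.default_community_truth()
        comp = np.asarray(truth.composition).copy()
        comp[0] += 0.1
        with pytest.raises(InvalidParameterError):
            synthio.default_community_truth(composition=tuple(comp))
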