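import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypoxomethyl import simdata, survstats
from hypoxomethyl.simdata import SimConfig, simulate_methylomes


def tiny(**kw):
    base = dict(
        n_patients=2,
        chrom_length_bp=100_000,
        n_cpg=2_000,
        n_planted_hyper=2,
        n_planted_hypo=2,
        n_array_samples=30,
        n_array_decoys=40,
        n_genes=30,
        hypoxia_gene_n=5,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_too_many_planted_cpgs(self):
        with pytest.raises(ValueError):
            SimConfig(n_cpg=50, n_planted_hyper=10, n_planted_hypo=10, planted_n_cpg=10)

    def test_bad_coverage(self):
        with pytest.raises(ValueError):
            tiny(mean_coverage=0)

    def test_bad_censor_rate(self):
        with pytest.raises(ValueError):
            tiny(censor_rate=1.0)


class TestMethylomes:
    def test_no_effect_case_latents_identical(self):
        _, truth = simulate_methylomes(tiny(planted_delta=0.0))
        tb = truth.true_betas
        tp = [c for c in tb.columns if c.endswith("_TP")]
        tn = [c for c in tb.columns if c.endswith("_TN")]
        assert np.array_equal(tb[tp].to_numpy(), tb[tn].to_numpy())

    def test_determinism_same_seed(self):
        s1, t1 = simulate_methylomes(tiny(seed=7))
        s2, t2 = simulate_methylomes(tiny(seed=7))
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.sites, b.sites)
        assert t1.planted_regions == t2.planted_regions

    def test_planted_hyper_fraction_matches_binomial_moments(self):
        # closed-form oracle: pooled meth/cov inside hyper regions across
        # hypoxic samples estimates base+0.4 with SE sqrt(p(1-p)/N)
        cfg = tiny(mean_coverage=30, planted_delta=0.4, seed=5)
        samples, truth = simulate_methylomes(cfg)
        hyp = [s for s in samples if truth.per_sample_hypoxia_label[s.sample_id] == "hypoxic"]
        base = simdata._region_baseline(cfg, "hyper")
        expected = base + 0.4
        meth = cov = 0
        for s in hyp:
            for iv, direction, _ in truth.planted_regions:
                if direction != "hyper":
                    continue
                sub = s.sites[(s.sites["pos"] >= iv.start) & (s.sites["pos"] < iv.end)]
                meth += sub["meth"].sum()
                cov += sub["cov"].sum()
        se = np.sqrt(expected * (1 - expected) / cov)
        assert abs(meth / cov - expected) < 3 * se

    def test_meth_never_exceeds_coverage(self):
        samples, _ = simulate_methylomes(tiny(seed=9))
        for s in samples:
            assert (s.sites["meth"] <= s.sites["cov"]).all()
            assert (s.sites["cov"] >= 1).all()

    def test_positions_strictly_increasing(self):
        samples, _ = simulate_methylomes(tiny())
        pos = samples[0].sites["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_planted_regions_disjoint_and_inside_chrom(self):
        cfg = tiny()
        _, truth = simulate_methylomes(cfg)
        ivs = sorted(iv for iv, _, _ in truth.planted_regions)
        assert all(ivs[i].end <= ivs[i + 1].start for i in range(len(ivs) - 1))
        assert all(0 <= iv.start and iv.end <= cfg.chrom_length_bp for iv in ivs)

    def test_infeasible_layout_rejected_at_config(self):
        with pytest.raises(ValueError, match="exceed"):
            tiny(chrom_length_bp=4_000, n_cpg=300, region_buffer_bp=3_000)

    def test_placement_error_when_packing_too_tight(self):
        # feasible on paper but effectively impossible to place at random
        with pytest.raises(simdata.PlacementError):
            simulate_methylomes(
                tiny(chrom_length_bp=12_500, n_cpg=500, region_buffer_bp=2_000)
            )

    def test_truth_json_round_trip(self, tmp_path):
        _, truth = simulate_methylomes(tiny())
        truth.to_json(tmp_path / "t.json")
        back = simdata.SimTruth.from_json(tmp_path / "t.json")
        assert back.planted_regions == truth.planted_regions
        assert back.per_sample_hypoxia_label == truth.per_sample_hypoxia_label
        assert back.true_signature_regions == truth.true_signature_regions
        pd.testing.assert_frame_equal(back.true_betas, truth.true_betas)


class TestArrayCohort:
    def test_null_probe_means_balanced(self):
        cfg = tiny(planted_delta=0.0, hypoxia_effect=0.0, n_array_samples=60)
        _, truth = simulate_methylomes(cfg)
        beta = simdata.simulate_array_cohort(cfg, truth)
        lab = truth.array_hypoxia_label
        hyp = [s for s in beta.values.index if lab[s] == "hypoxic"]
        nor = [s for s in beta.values.index if lab[s] == "normoxic"]
        gaps = beta.values.loc[hyp].mean() - beta.values.loc[nor].mean()
        assert abs(gaps.mean()) < 0.02 and gaps.abs().max() < 0.1

    def test_decoy_difference_centered_at_zero(self):
        cfg = tiny(n_array_samples=80, n_array_decoys=200, seed=2)
        _, truth = simulate_methylomes(cfg)
        beta = simdata.simulate_array_cohort(cfg, truth)
        lab = truth.array_hypoxia_label
        hyp = [s for s in beta.values.index if lab[s] == "hypoxic"]
        nor = [s for s in beta.values.index if lab[s] == "normoxic"]
        decoys = [c for c in beta.values.columns if "decoy" in c]
        gaps = beta.values.loc[hyp, decoys].mean() - beta.values.loc[nor, decoys].mean()
        assert abs(gaps.mean()) < 0.01

    def test_planted_probes_detected_by_ranksum_on_latent_groups(self):
        # oracle: rank-sum straight against the latent labels
        cfg = tiny(planted_delta=0.3, n_array_samples=100, seed=4)
        _, truth = simulate_methylomes(cfg)
        beta = simdata.simulate_array_cohort(cfg, truth)
        lab = truth.array_hypoxia_label
        hyp = np.array([lab[s] == "hypoxic" for s in beta.values.index])
        planted = [c for c in beta.values.columns if "region" in c]
        from statsmodels.stats.multitest import multipletests

        p = np.array(
            [
                stats.mannwhitneyu(
                    beta.values.loc[hyp, c], beta.values.loc[~hyp, c]
                ).pvalue
                for c in beta.values.columns
            ]
        )
        q = multipletests(p, method="fdr_bh")[1]
        qmap = dict(zip(beta.values.columns, q))
        detected = sum(qmap[c] < 0.05 for c in planted)
        assert detected >= 0.95 * len(planted)


class TestExpression:
    def test_no_effect_groups_indistinguishable(self):
        cfg = tiny(hypoxia_effect=0.0, n_array_samples=60, seed=6)
        _, truth = simulate_methylomes(cfg)
        expr = simdata.simulate_expression(cfg, truth)
        lab = truth.array_hypoxia_label
        hyp = np.array([lab[s] == "hypoxic" for s in expr.values.index])
        genes = simdata.hypoxia_gene_ids(cfg)
        score = (expr.values[genes] > expr.values[genes].median()).sum(axis=1)
        p = stats.mannwhitneyu(score[hyp], score[~hyp]).pvalue
        assert p > 0.01

    def test_strong_effect_recovers_labels(self):
        cfg = tiny(hypoxia_effect=3.0, n_array_samples=100, seed=8)
        _, truth = simulate_methylomes(cfg)
        expr = simdata.simulate_expression(cfg, truth)
        lab = truth.array_hypoxia_label
        genes = simdata.hypoxia_gene_ids(cfg)
        score = (expr.values[genes] > expr.values[genes].median()).sum(axis=1)
        pred = score > score.median()
        truth_vec = np.array([lab[s] == "hypoxic" for s in expr.values.index])
        agree = (pred.to_numpy() == truth_vec).mean()
        assert agree >= 0.95

    def test_fixed_seed_identical(self):
        cfg = tiny(seed=12)
        _, truth1 = simulate_methylomes(cfg)
        _, truth2 = simulate_methylomes(cfg)
        e1 = simdata.simulate_expression(cfg, truth1)
        e2 = simdata.simulate_expression(cfg, truth2)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_label_consistency_between_array_and_expression(self):
        cfg = tiny(seed=13)
        _, ta = simulate_methylomes(cfg)
        _, tb = simulate_methylomes(cfg)
        simdata.simulate_array_cohort(cfg, ta)     # labels created by array first
        simdata.simulate_expression(cfg, tb)       # ... or by expression first
        assert ta.array_hypoxia_label == tb.array_hypoxia_label


class TestSurvival:
    def test_no_censoring_all_events(self):
        out = simdata.simulate_survival(np.arange(20.0), 1.0, 0.0, seed=1)
        assert all(o.event for o in out)

    def test_event_fraction_tracks_censor_rate(self):
        rng = np.random.default_rng(0)
        out = simdata.simulate_survival(rng.normal(0, 1, 2000), 0.5, 0.4, seed=2)
        frac = np.mean([o.event for o in out])
        assert abs(frac - 0.6) < 0.06

    def test_null_logrank_rejection_rate(self):
        # oracle: type-I error of the median-split log-rank near 5%
        rej = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            scores = rng.normal(0, 1, 80)
            out = simdata.simulate_survival(scores, 0.0, 0.2, seed=10_000 + rep)
            df = pd.DataFrame({"sample_id": [o.sample_id for o in out], "score": scores})
            grp = survstats.dichotomize(df)
            hi = [o for o in out if grp[o.sample_id] == "high"]
            lo = [o for o in out if grp[o.sample_id] == "low"]
            rej += survstats.log_rank(hi, lo).p < 0.05
        assert 0.01 <= rej / reps <= 0.10

    def test_cox_recovers_planted_log_hr(self):
        coefs = []
        for seed in range(8):
            rng = np.random.default_rng(500 + seed)
            scores = rng.normal(0, 1, 200)
            out = simdata.simulate_survival(scores, 1.0, 0.3, seed=seed)
            coefs.append(survstats.cox_univariate(scores, out).coef)
        assert abs(np.mean(coefs) - 1.0) < 0.25

    def test_rejects_nonfinite_scores(self):
        with pytest.raises(ValueError):
            simdata.simulate_survival([1.0, np.nan], 1.0, 0.2, seed=1)
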