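import numpy as np
import pandas as pd
import pytest

from hypoxomethyl import hypoxsig, simdata
from hypoxomethyl.dmrcall import Dmr
from hypoxomethyl.hypoxsig import (
    HypoxiaGeneSet,
    RnaHypoxiaScore,
    build_signature,
    probe_differential,
    rna_hypoxia_score,
    score_cohort,
)
from hypoxomethyl.methio import GenomicInterval
from hypoxomethyl.simdata import CohortMatrix


def expr_matrix(values, genes, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return CohortMatrix(pd.DataFrame(values, index=samples, columns=genes), None, "expression")


def beta_matrix(values, probes, positions, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    coords = pd.DataFrame(
        {"feature": probes, "chrom": "chrT", "start": positions, "end": [p + 1 for p in positions]}
    )
    return CohortMatrix(pd.DataFrame(values, index=samples, columns=probes), coords, "beta")


def hyper_dmr(start, end):
    return Dmr(GenomicInterval("chrT", start, end), 10, 0.3, "hyper", 8)


class TestRnaScore:
    def test_sample_above_every_median_gets_max_score(self):
        genes = ["g1", "g2", "g3"]
        vals = [[1, 1, 1], [2, 2, 2], [9, 9, 9]]
        scores = rna_hypoxia_score(expr_matrix(vals, genes), HypoxiaGeneSet(tuple(genes)))
        assert scores[2].score == 3

    def test_constant_matrix_all_zero_scores(self):
        genes = ["g1", "g2"]
        vals = [[5, 5], [5, 5], [5, 5]]
        scores = rna_hypoxia_score(expr_matrix(vals, genes), HypoxiaGeneSet(tuple(genes)))
        assert all(s.score == 0 for s in scores)
        assert all(s.group == "low" for s in scores)  # ties below the median

    def test_hand_counted_scores(self):
        # gene medians: g1 -> 2.5, g2 -> 20
        genes = ["g1", "g2"]
        vals = [[1, 10], [2, 30], [3, 15], [4, 40]]
        scores = rna_hypoxia_score(expr_matrix(vals, genes), HypoxiaGeneSet(tuple(genes)))
        assert [s.score for s in scores] == [0, 1, 1, 2]
        assert [s.group for s in scores] == ["low", "low", "low", "high"]

    def test_missing_genes_dropped_with_warning(self):
        genes = ["g1"]
        vals = [[1], [2], [3]]
        with pytest.warns(UserWarning, match="absent"):
            scores = rna_hypoxia_score(
                expr_matrix(vals, genes), HypoxiaGeneSet(("g1", "ghost"))
            )
        assert len(scores) == 3

    def test_no_gene_found_error(self):
        with pytest.raises(ValueError, match="ghost"):
            rna_hypoxia_score(expr_matrix([[1], [2]], ["g1"]), HypoxiaGeneSet(("ghost",)))


class TestProbeDifferential:
    def groups(self, n_high, n_low):
        return [
            RnaHypoxiaScore(f"s{i}", 1.0 if i < n_high else 0.0, "high" if i < n_high else "low")
            for i in range(n_high + n_low)
        ]

    def test_identical_groups_nothing_retained(self):
        rng = np.random.default_rng(1)
        vals = np.tile(rng.random(10), (8, 1))  # every probe constant across samples
        beta = beta_matrix(vals, [f"p{i}" for i in range(10)], list(range(0, 1000, 100)))
        res = probe_differential(beta, self.groups(4, 4))
        assert (res["p"] == 1.0).all()
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert not ((res["q"] < 0.05) & res["hyper_in_high"]).any()

    def test_label_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(2)
        vals = rng.random((10, 6))
        beta = beta_matrix(vals, [f"p{i}" for i in range(6)], list(range(0, 600, 100)))
        g = self.groups(5, 5)
        swapped = [
            RnaHypoxiaScore(x.sample_id, x.score, "low" if x.group == "high" else "high")
            for x in g
        ]
        a = probe_differential(beta, g)
        b = probe_differential(beta, swapped)
        assert np.allclose(a["p"], b["p"])
        assert (a["hyper_in_high"] ^ b["hyper_in_high"]).all()

    def test_planted_probes_detected(self, small_study):
        cfg, _, truth = small_study
        beta = simdata.simulate_array_cohort(cfg, truth)
        lab = truth.array_hypoxia_label
        groups = [
            RnaHypoxiaScore(s, 1.0, "high" if lab[s] == "hypoxic" else "low")
            for s in beta.values.index
        ]
        res = probe_differential(beta, groups).set_index("probe_id")
        hyper_probes = [
            f"probe_region_{j + 1:03d}"
            for j, (_, d, _) in enumerate(truth.planted_regions)
            if d == "hyper"
        ]
        hit = res.loc[hyper_probes]
        assert ((hit["q"] < 0.05) & hit["hyper_in_high"]).mean() >= 0.95


class TestBuildSignature:
    def probe_frame(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "q", "hyper_in_high"])

    def test_no_probe_passes_empty_signature(self):
        probes = self.probe_frame([("p1", "chrT", 150, 0.5, True)])
        with pytest.warns(UserWarning, match="empty signature"):
            model = build_signature([hyper_dmr(100, 300)], probes)
        assert model.n_regions == 0

    def test_probe_on_half_open_boundary_not_retained(self):
        probes = self.probe_frame([("p1", "chrT", 300, 0.001, True)])
        with pytest.warns(UserWarning):
            model = build_signature([hyper_dmr(100, 300)], probes)
        assert model.n_regions == 0
        inside = self.probe_frame([("p1", "chrT", 299, 0.001, True)])
        model = build_signature([hyper_dmr(100, 300)], inside)
        assert model.n_regions == 1
        assert model.supporting_probes["chrT:100-300"] == ["p1"]

    def test_hypo_dmr_rejected(self):
        d = Dmr(GenomicInterval("chrT", 0, 300), 5, -0.3, "hypo", 5)
        with pytest.raises(ValueError):
            build_signature([d], self.probe_frame([]))

    def test_monotone_in_q_cut(self):
        probes = self.probe_frame(
            [("p1", "chrT", 150, 0.01, True), ("p2", "chrT", 450, 0.04, True)]
        )
        dmrs = [hyper_dmr(100, 300), hyper_dmr(400, 700)]
        with pytest.warns(UserWarning):
            small = build_signature(dmrs, probes, q_cut=0.005)
        mid = build_signature(dmrs, probes, q_cut=0.02)
        big = build_signature(dmrs, probes, q_cut=0.05)
        keys = lambda m: {hypoxsig.region_key(r) for r in m.regions}
        assert keys(small) <= keys(mid) <= keys(big)

    def test_save_load_round_trip(self, tmp_path):
        probes = self.probe_frame([("p1", "chrT", 150, 0.01, True)])
        model = build_signature([hyper_dmr(100, 300)], probes)
        model.save(tmp_path / "model")
        back = hypoxsig.SignatureModel.load(tmp_path / "model")
        assert back.regions == model.regions
        assert back.supporting_probes == model.supporting_probes


class TestScoreCohort:
    def test_all_zero_methylation_scores_zero(self):
        beta = beta_matrix(np.zeros((3, 2)), ["p1", "p2"], [150, 450])
        model = hypoxsig.SignatureModel(
            [GenomicInterval("chrT", 100, 300), GenomicInterval("chrT", 400, 600)]
        )
        scores = score_cohort(model, beta)
        assert (scores["score"] == 0).all()
        assert (scores["n_regions_used"] == 2).all()

    def test_three_region_mean(self):
        vals = np.array([[0.2, 0.4, 0.6]])
        beta = beta_matrix(vals, ["p1", "p2", "p3"], [150, 450, 750])
        model = hypoxsig.SignatureModel(
            [
                GenomicInterval("chrT", 100, 300),
                GenomicInterval("chrT", 400, 600),
                GenomicInterval("chrT", 700, 900),
            ]
        )
        assert score_cohort(model, beta)["score"].iloc[0] == pytest.approx(0.4)

    def test_region_and_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.random((4, 3))
        beta = beta_matrix(vals, ["p1", "p2", "p3"], [150, 450, 750])
        regions = [
            GenomicInterval("chrT", 100, 300),
            GenomicInterval("chrT", 400, 600),
            GenomicInterval("chrT", 700, 900),
        ]
        a = score_cohort(hypoxsig.SignatureModel(regions), beta).set_index("sample_id")
        b = score_cohort(hypoxsig.SignatureModel(regions[::-1]), beta).set_index("sample_id")
        shuffled = CohortMatrix(beta.values.iloc[[2, 0, 3, 1]], beta.feature_coords, "beta")
        c = score_cohort(hypoxsig.SignatureModel(regions), shuffled).set_index("sample_id")
        pd.testing.assert_series_equal(a["score"], b["score"])
        pd.testing.assert_series_equal(a["score"].sort_index(), c["score"].sort_index())

    def test_wgbs_scoring_coverage_weighted(self):
        from hypoxomethyl.methio import MethylomeSample

        sites = pd.DataFrame(
            {"chrom": ["chrT", "chrT"], "pos": [150, 200], "cov": [10, 30], "meth": [10, 0]}
        )
        s = MethylomeSample("w1", sites, "TP")
        model = hypoxsig.SignatureModel([GenomicInterval("chrT", 100, 300)])
        scores = score_cohort(model, [s])
        assert scores["score"].iloc[0] == pytest.approx(10 / 40)

    def test_group_separation_matches_planted_effect(self, small_study):
        # closed-form expectation: high-group mean exceeds low-group mean by
        # about planted_delta at signature regions (label noise aside)
        cfg, _, truth = small_study
        beta = simdata.simulate_array_cohort(cfg, truth)
        model = hypoxsig.SignatureModel(list(truth.true_signature_regions))
        scores = score_cohort(model, beta).set_index("sample_id")
        lab = truth.array_hypoxia_label
        hi = scores.loc[[s for s in scores.index if lab[s] == "hypoxic"], "score"].mean()
        lo = scores.loc[[s for s in scores.index if lab[s] == "normoxic"], "score"].mean()
        assert hi - lo == pytest.approx(cfg.planted_delta, abs=0.05)

    def test_empty_model_error(self):
        with pytest.raises(ValueError):
            score_cohort(hypoxsig.SignatureModel([]), beta_matrix(np.zeros((2, 1)), ["p1"], [5]))
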