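import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoscreen.essentiality import (
    BootstrapConfig,
    DensityPair,
    FoldChangeTable,
    GaussianKde,
    ParametricDensity,
    fit_densities,
    gene_bayes_factor,
    genotype_bf,
    guide_log_fold_change,
    monotone_lr_envelope,
    score_screen,
    silverman_bandwidth,
)
from isoscreen.screen_model import (
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    ReferenceGeneSets,
)


def gaussian_pair(mu_e=-3.0, mu_n=0.0, sd=1.0):
    """Parametric hook: closed-form Gaussian densities."""
    return DensityPair(
        essential=ParametricDensity(lambda x: stats.norm.pdf(x, mu_e, sd)),
        nonessential=ParametricDensity(lambda x: stats.norm.pdf(x, mu_n, sd)),
    )


class TestGuideLogFoldChange:
    def test_identical_sample_and_plasmid_gives_zero(self, tiny_library):
        counts = np.tile(np.array([[10], [20], [30], [40], [50]]), (1, 2))
        cm = CountMatrix(tiny_library.guide_ids, ["plasmid", "s1"], counts)
        fc = guide_log_fold_change(cm, "plasmid", alpha=5)
        assert np.allclose(fc.fc["s1"], 0.0)

    def test_closed_form_example(self):
        # c=10 vs plasmid 100, alpha=5; second guide pads both columns to
        # equal depth 200, so fc(g1) = log2(15/105) exactly
        cm = CountMatrix(
            ["g1", "g2"], ["plasmid", "s1"], np.array([[100, 10], [100, 190]])
        )
        fc = guide_log_fold_change(cm, "plasmid", alpha=5)
        assert fc.fc.loc["g1", "s1"] == pytest.approx(math.log2(15 / 105), abs=1e-12)
        assert fc.fc.loc["g1", "s1"] == pytest.approx(-2.8074, abs=1e-4)

    def test_zero_count_finite_with_pseudocount(self):
        cm = CountMatrix(["g1", "g2"], ["plasmid", "s1"], np.array([[50, 0], [50, 100]]))
        fc = guide_log_fold_change(cm, "plasmid", alpha=5)
        val = fc.fc.loc["g1", "s1"]
        assert np.isfinite(val) and val < 0

    def test_zero_depth_errors(self):
        cm = CountMatrix(["g1"], ["plasmid", "s1"], np.array([[5, 0]]))
        with pytest.raises(ValueError, match="zero depth"):
            guide_log_fold_change(cm, "plasmid")

    def test_alpha_must_be_positive(self, tiny_counts):
        with pytest.raises(ValueError, match="alpha"):
            guide_log_fold_change(tiny_counts, "plasmid", alpha=0)

    def test_scale_invariance_of_one_sample(self):
        # multiplying a sample's counts (hence depth) by k leaves fc unchanged
        # exactly in the alpha -> 0 limit with positive counts
        rng = np.random.default_rng(2)
        base = rng.integers(10, 100, size=(6, 2))
        cm1 = CountMatrix([f"g{i}" for i in range(6)], ["plasmid", "s1"], base)
        scaled = base.copy()
        scaled[:, 1] *= 7
        cm2 = CountMatrix([f"g{i}" for i in range(6)], ["plasmid", "s1"], scaled)
        f1 = guide_log_fold_change(cm1, "plasmid", alpha=1e-9)
        f2 = guide_log_fold_change(cm2, "plasmid", alpha=1e-9)
        assert np.allclose(f1.fc, f2.fc, atol=1e-6)


class TestGaussianKde:
    def test_silverman_formula(self):
        data = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 10.0])
        sd = data.std(ddof=1)
        iqr = np.percentile(data, 75) - np.percentile(data, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * len(data) ** -0.2
        assert silverman_bandwidth(data) == pytest.approx(expected, rel=1e-12)

    def test_peaks_at_training_modes(self):
        kde_a = GaussianKde([-3.0] * 20, bandwidth=0.1)
        kde_b = GaussianKde([0.0] * 20, bandwidth=0.1)
        xs = np.linspace(-4, 1, 501)
        assert xs[np.argmax(kde_a(xs))] == pytest.approx(-3, abs=0.02)
        assert xs[np.argmax(kde_b(xs))] == pytest.approx(0, abs=0.02)

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, 40)
        h = 0.3
        kde = GaussianKde(data, bandwidth=h)
        xs = np.linspace(data.min(), data.max(), 23)
        for x in xs:
            brute = sum(
                math.exp(-0.5 * ((x - xi) / h) ** 2) for xi in data
            ) / (len(data) * h * math.sqrt(2 * math.pi))
            assert kde(x)[0] == pytest.approx(brute, abs=1e-9)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(4)
        kde = GaussianKde(rng.normal(-1, 0.7, 200))
        xs = np.linspace(kde.lo, kde.hi, 20001)
        integral = np.trapezoid(kde(xs), xs)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_floor_applies(self):
        kde = GaussianKde([0.0, 0.1], bandwidth=1e-3, floor=1e-12, clamp_pad=50)
        assert kde(0.04)[0] == 1e-12

    def test_evaluation_clamped_to_support(self):
        kde = GaussianKde([0.0, 1.0], bandwidth=0.2)
        assert kde(-100)[0] == kde(kde.lo)[0]
        assert kde(+100)[0] == kde(kde.hi)[0]

    def test_degenerate_training_data_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            silverman_bandwidth(np.array([1.0, 1.0, 1.0]))


class TestDensityPair:
    def test_symmetric_training_crossing_at_midpoint(self):
        a = GaussianKde([-3.2, -3.1, -3.0, -2.9, -2.8], bandwidth=0.2)
        b = GaussianKde([-0.2, -0.1, 0.0, 0.1, 0.2], bandwidth=0.2)
        pair = DensityPair(a, b)
        assert pair.raw_log2_ratio(-1.5)[0] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_envelope_is_non_increasing_and_bounded(self):
        rng = np.random.default_rng(0)
        pair = DensityPair(
            GaussianKde(rng.normal(-2, 0.6, 200)),
            GaussianKde(rng.normal(0, 0.25, 200)),
        )
        mono = monotone_lr_envelope(pair)
        xs = np.linspace(-8, 4, 400)
        lr = mono.log2_ratio(xs)
        assert np.all(np.diff(lr) <= 1e-12)
        assert lr[0] == pytest.approx(lr.max())


class TestFitDensities:
    def _fc_table(self, library, rng):
        data = {
            "s1": rng.normal(0, 1, len(library)),
            "s2": rng.normal(0, 1, len(library)),
        }
        df = pd.DataFrame(data, index=pd.Index(library.guide_ids, name="guide_id"))
        return FoldChangeTable(df, "plasmid", 5.0, 1e7)

    def _library(self, n_genes=12, guides=2):
        recs = []
        rng = np.random.default_rng(0)
        seen = set()
        for i in range(n_genes):
            for j in range(guides):
                while True:
                    seq = "".join(rng.choice(list("ACGT"), 20))
                    if seq not in seen:
                        seen.add(seq)
                        break
                recs.append(GuideRecord(f"G{i}_g{j}", f"G{i}", seq))
        return GuideLibrary(recs)

    def test_underpopulated_class_names_class(self):
        lib = self._library()
        fc = self._fc_table(lib, np.random.default_rng(1))
        refsets = ReferenceGeneSets(frozenset({"G0"}), frozenset({"G1", "G2", "G3"}))
        with pytest.raises(ValueError, match="essential"):
            fit_densities(fc, lib, refsets)

    def test_shared_bandwidth(self):
        lib = self._library()
        fc = self._fc_table(lib, np.random.default_rng(1))
        refsets = ReferenceGeneSets(
            frozenset({f"G{i}" for i in range(5)}),
            frozenset({f"G{i}" for i in range(5, 10)}),
        )
        pair = fit_densities(fc, lib, refsets, monotone=False)
        assert pair.essential.bandwidth == pair.nonessential.bandwidth


class TestGeneBayesFactor:
    def _one_gene_setup(self, fcs):
        lib = GuideLibrary(
            [
                GuideRecord("g1", "GENE", "ACGTACGTACGTACGTACGT"),
                GuideRecord("g2", "GENE", "TCGTACGTACGTACGTACGT"),
                GuideRecord("g3", "GENE", "GCGTACGTACGTACGTACGT"),
            ]
        )
        df = pd.DataFrame(
            {"s1": fcs}, index=pd.Index(["g1", "g2", "g3"], name="guide_id")
        )
        return lib, FoldChangeTable(df, "plasmid", 5.0, 1e7)

    def test_parametric_closed_form_single_obs(self):
        lib, fc = self._one_gene_setup([-3.0, -3.0, -3.0])
        out = gene_bayes_factor(fc, gaussian_pair(), lib)
        # per observation: 4.5 nats = 4.5/ln2 bits; 3 observations
        per_obs = 4.5 / math.log(2)
        assert per_obs == pytest.approx(6.4924, abs=1e-3)
        assert out.loc["GENE", "bf"] == pytest.approx(3 * per_obs, abs=1e-9)
        assert out.loc["GENE", "bf"] == pytest.approx(19.477, abs=1e-3)

    def test_equal_density_point_is_zero(self):
        lib, fc = self._one_gene_setup([-1.5, -1.5, -1.5])
        out = gene_bayes_factor(fc, gaussian_pair(), lib)
        assert out.loc["GENE", "bf"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_analytic_quadratic_form(self):
        rng = np.random.default_rng(8)
        fcs = rng.normal(-1, 2, 3)
        lib, fc = self._one_gene_setup(list(fcs))
        out = gene_bayes_factor(fc, gaussian_pair(), lib)
        # log LR for N(-3,1) vs N(0,1): (x^2 - (x+3)^2)/2 = -(6x + 9)/2 nats
        expected = sum(-(6 * x + 9) / 2 for x in fcs) / math.log(2)
        assert out.loc["GENE", "bf"] == pytest.approx(expected, abs=1e-9)

    def test_additive_over_guides(self):
        rng = np.random.default_rng(3)
        fcs = list(rng.normal(-1, 1, 3))
        lib, fc = self._one_gene_setup(fcs)
        pair = gaussian_pair()
        per_guide = pair.log2_ratio(np.array(fcs))
        out = gene_bayes_factor(fc, pair, lib)
        assert out.loc["GENE", "bf"] == pytest.approx(per_guide.sum(), abs=1e-12)

    def test_gene_absent_from_fc_absent_from_output(self):
        lib = GuideLibrary(
            [
                GuideRecord("g1", "GENE", "ACGTACGTACGTACGTACGT"),
                GuideRecord("h1", "OTHER", "TCGTACGTACGTACGTACGT"),
            ]
        )
        df = pd.DataFrame({"s1": [-2.0]}, index=pd.Index(["g1"], name="guide_id"))
        fc = FoldChangeTable(df, "plasmid", 5.0, 1e7)
        out = gene_bayes_factor(fc, gaussian_pair(), lib)
        assert "OTHER" not in out.index and "GENE" in out.index

    def test_control_guides_excluded(self, tiny_library):
        df = pd.DataFrame(
            {"s1": np.zeros(len(tiny_library))},
            index=pd.Index(tiny_library.guide_ids, name="guide_id"),
        )
        fc = FoldChangeTable(df, "plasmid", 5.0, 1e7)
        out = gene_bayes_factor(fc, gaussian_pair(), tiny_library)
        assert set(out.index) == {"GA", "GB"}

    def test_kde_converges_to_parametric(self):
        rng = np.random.default_rng(12)
        ess_train = rng.normal(-3, 1, 20000)
        non_train = rng.normal(0, 1, 20000)
        pair = DensityPair(GaussianKde(ess_train), GaussianKde(non_train))
        x = -2.0
        closed = -(6 * x + 9) / 2 / math.log(2)
        assert pair.raw_log2_ratio(x)[0] == pytest.approx(closed, abs=0.15)

    def test_degenerate_bootstrap_matches_point_estimate(self):
        lib = GuideLibrary(
            [
                GuideRecord(f"G{i}_g{j}", f"G{i}", seq)
                for i, j, seq in [
                    (i, j, "".join(np.random.default_rng(i * 7 + j).choice(list("ACGT"), 20)))
                    for i in range(14)
                    for j in range(2)
                ]
            ]
        )
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"s1": rng.normal(-1, 1, len(lib))},
            index=pd.Index(lib.guide_ids, name="guide_id"),
        )
        fc = FoldChangeTable(df, "plasmid", 5.0, 1e7)
        refsets = ReferenceGeneSets(
            frozenset({f"G{i}" for i in range(6)}),
            frozenset({f"G{i}" for i in range(6, 12)}),
        )
        pair = fit_densities(fc, lib, refsets)
        boot = BootstrapConfig(n_iter=1, refsets=refsets, resample=False)
        out = gene_bayes_factor(fc, pair, lib, bootstrap=boot, seed=0)
        assert np.allclose(out["boot_mean"], out["bf"], atol=1e-9)
        assert (out["boot_sd"] == 0).all()


class TestGenotypeBf:
    def _per_line(self, values):
        rows = []
        for (gene, sample), bf in values.items():
            rows.append({"gene": gene, "sample": sample, "bf": bf})
        return pd.DataFrame(rows)

    def test_mean_of_three_lines(self, tiny_sheet):
        per = self._per_line(
            {("G", "ko_1"): 1.0, ("G", "ko_2"): 2.0, ("G", "wt_1"): 3.0}
        )
        out = genotype_bf(per, tiny_sheet)
        assert out.loc["G", "knockout"] == pytest.approx(1.5)
        assert out.loc["G", "wildtype"] == pytest.approx(3.0)

    def test_single_line_identity(self, tiny_sheet):
        per = self._per_line({("G", "ko_1"): 2.5})
        out = genotype_bf(per, tiny_sheet)
        assert out.loc["G", "knockout"] == 2.5

    def test_mean_matches_brute_force(self, tiny_sheet):
        rng = np.random.default_rng(7)
        values = {}
        for gene in ["A", "B", "C"]:
            for sample in ["ko_1", "ko_2", "wt_1", "wt_2"]:
                values[(gene, sample)] = rng.normal()
        out = genotype_bf(self._per_line(values), tiny_sheet)
        for gene in ["A", "B", "C"]:
            expected = np.mean([values[(gene, s)] for s in ["ko_1", "ko_2"]])
            assert out.loc[gene, "knockout"] == pytest.approx(expected, abs=1e-12)

    def test_pooled_and_median(self, tiny_sheet):
        per = self._per_line(
            {("G", "ko_1"): 1.0, ("G", "ko_2"): 5.0}
        )
        assert genotype_bf(per, tiny_sheet, "pooled").loc["G", "knockout"] == 6.0
        assert genotype_bf(per, tiny_sheet, "median").loc["G", "knockout"] == 3.0

    def test_unknown_aggregation(self, tiny_sheet):
        with pytest.raises(ValueError, match="aggregation"):
            genotype_bf(self._per_line({("G", "ko_1"): 1.0}), tiny_sheet, "mode")


class TestScoreScreen:
    def test_end_to_end_on_simulated_screen(self, small_screen):
        from isoscreen import synthetic_data as sd

        refsets = sd.reference_sets_from_truth(
            small_screen.truth, n_nonessential=40, seed=0
        )
        geno, per_line = score_screen(
            small_screen.counts,
            small_screen.sheet,
            small_screen.library,
            refsets,
        )
        assert set(geno.columns) == {"knockout", "wildtype"}
        assert len(geno) == len(small_screen.library.targeting_genes)
        # planted core essentials should score far above neutrals in both arms
        ess_genes = small_screen.truth.genes_of_class("core_essential")
        neutral = small_screen.truth.genes_of_class("neutral")
        assert geno.loc[ess_genes, "wildtype"].mean() > geno.loc[neutral, "wildtype"].mean() + 10
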