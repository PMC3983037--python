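import math

import numpy as np
import pytest

from gremlpower import (
    compute_grm,
    make_liability_model,
    run_replicates,
    simulate_case_control,
    simulate_genotypes,
    simulate_phenotypes,
)
from gremlpower.simulate import SimulationConfig


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="design"):
            SimulationConfig(design="nope")
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="n_causal"):
            SimulationConfig(m=100, n_causal=101)
        with pytest.raises(ValueError, match="n2"):
            SimulationConfig(design="bivariate_different_samples")
        with pytest.raises(ValueError, match="prevalence"):
            SimulationConfig(design="case_control")

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "design: univariate\nn: 120\nm: 300\nh2: 0.3\nn_replicates: 2\nseed: 5\n"
            "maf_range: [0.1, 0.5]\n"
        )
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.n == 120 and cfg.h2 == 0.3 and cfg.maf_range == (0.1, 0.5)

    def test_case_control_pool_multiplier_default_scales_with_ascertainment(self):
        cfg = SimulationConfig(design="case_control", prevalence=0.05,
                               case_fraction=0.5, n=100, m=50)
        assert cfg.pool_multiplier_resolved == pytest.approx(20.0)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n=50, m=100, seed=123)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_sample_frequencies_track_population_frequencies(self):
        cfg = SimulationConfig(n=5000, m=50, maf_range=(0.2, 0.4), seed=1)
        g = simulate_genotypes(cfg)
        freqs = g.allele_frequencies()
        assert freqs.min() > 0.1 and freqs.max() < 0.5
        # binomial sampling error at n=5000 is ~0.005
        assert np.all((freqs > 0.2 - 0.05) & (freqs < 0.4 + 0.05))

    def test_grm_offdiagonal_variance_near_inverse_snp_count(self, small_grm):
        assert small_grm.offdiagonal().var() == pytest.approx(1 / 2000, rel=0.15)


class TestPhenotypes:
    def test_realized_variances_exact(self):
        cfg = SimulationConfig(n=200, m=400, h2=0.37, seed=2)
        g = simulate_genotypes(cfg, rng=np.random.default_rng(2))
        draw = simulate_phenotypes(g, cfg, np.random.default_rng(3))
        gv = draw.genetic_values[0]
        assert gv.var() == pytest.approx(0.37, rel=1e-10)
        assert (draw.y - gv).var() == pytest.approx(0.63, rel=1e-10)

    def test_degenerate_heritabilities(self):
        g = simulate_genotypes(SimulationConfig(n=100, m=200, seed=4),
                               rng=np.random.default_rng(4))
        pure_noise = simulate_phenotypes(
            g, SimulationConfig(n=100, m=200, h2=0.0, seed=4), np.random.default_rng(5)
        )
        assert np.all(pure_noise.genetic_values[0] == 0)
        pure_genetic = simulate_phenotypes(
            g, SimulationConfig(n=100, m=200, h2=1.0, seed=4), np.random.default_rng(5)
        )
        assert (pure_genetic.y - pure_genetic.genetic_values[0]).var() == pytest.approx(0.0)

    def test_correlated_effects_hit_target_genetic_correlation(self):
        cfg = SimulationConfig(
            design="bivariate_same_sample", n=400, m=1000, h2=0.5, rg=0.4, seed=6
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(6))
        rng = np.random.default_rng(7)
        corrs = []
        for _ in range(40):
            draw = simulate_phenotypes(g, cfg, rng)
            corrs.append(np.corrcoef(*draw.genetic_values)[0, 1])
        corrs = np.array(corrs)
        sem = corrs.std(ddof=1) / math.sqrt(len(corrs))
        assert abs(corrs.mean() - 0.4) < 3 * sem + 0.02

    def test_shared_fraction_mechanism_hits_target(self):
        cfg = SimulationConfig(
            design="bivariate_same_sample", n=400, m=1000, n_causal=500,
            h2=0.5, rg=0.4, rg_mechanism="shared_fraction", seed=8,
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(8))
        rng = np.random.default_rng(9)
        corrs = np.array(
            [np.corrcoef(*simulate_phenotypes(g, cfg, rng).genetic_values)[0, 1]
             for _ in range(40)]
        )
        sem = corrs.std(ddof=1) / math.sqrt(len(corrs))
        assert abs(corrs.mean() - 0.4) < 3 * sem + 0.02

    def test_unachievable_shared_fraction_suggests_alternative(self):
        cfg = SimulationConfig(
            design="bivariate_same_sample", n=50, m=100, n_causal=3, rg=0.5,
            rg_mechanism="shared_fraction", seed=1,
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(1))
        with pytest.raises(ValueError, match="correlated_effects"):
            simulate_phenotypes(g, cfg, np.random.default_rng(2))

    def test_phenotypic_correlation_composition(self):
        cfg = SimulationConfig(
            design="bivariate_same_sample", n=2000, m=300, h2=0.4, h2_2=0.6,
            rg=0.5, re=0.3, seed=10,
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(10))
        rng = np.random.default_rng(11)
        rps = np.array(
            [np.corrcoef(*simulate_phenotypes(g, cfg, rng).phenotypes)[0, 1]
             for _ in range(30)]
        )
        expected = 0.5 * math.sqrt(0.4 * 0.6) + 0.3 * math.sqrt(0.6 * 0.4)
        assert rps.mean() == pytest.approx(expected, abs=0.03)


class TestCaseControl:
    def test_unascertained_pool_case_fraction_matches_prevalence(self):
        cfg = SimulationConfig(
            design="case_control", n=400, m=200, h2=0.3, prevalence=0.5,
            pool_multiplier=5, seed=12,
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(12))
        sample = simulate_case_control(g, cfg, np.random.default_rng(13))
        assert sample.status.mean() == pytest.approx(cfg.case_fraction)

    def test_cases_carry_higher_genetic_values(self):
        cfg = SimulationConfig(
            design="case_control", n=400, m=300, h2=0.5, prevalence=0.1, seed=14
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(14))
        sample = simulate_case_control(g, cfg, np.random.default_rng(15))
        cases = sample.genetic_values[sample.status == 1]
        controls = sample.genetic_values[sample.status == 0]
        assert cases.mean() > controls.mean() + 0.2

    def test_insufficient_cases_reports_achievable_maximum(self):
        cfg = SimulationConfig(
            design="case_control", n=500, m=100, h2=0.3, prevalence=0.01,
            pool_multiplier=2, seed=16,
        )
        g = simulate_genotypes(cfg, rng=np.random.default_rng(16))
        with pytest.raises(ValueError, match="achievable"):
            simulate_case_control(g, cfg, np.random.default_rng(17))


class TestRunReplicates:
    def test_deterministic_and_reports_constant_theory_se(self):
        cfg = SimulationConfig(design="univariate", n=200, m=500, h2=0.4,
                               n_replicates=5, seed=20)
        a = run_replicates(cfg)
        b = run_replicates(cfg)
        assert a.summary == b.summary
        assert len(a.replicates) == 5
        # theory SE does not depend on the heritability level
        other = run_replicates(
            SimulationConfig(design="univariate", n=200, m=500, h2=0.8,
                             n_replicates=5, seed=20)
        )
        assert a.summary["se_theory_inv_m"] == other.summary["se_theory_inv_m"]
        assert a.summary["se_theory_empirical"] == other.summary["se_theory_empirical"]

    def test_report_csv_written_with_summary_header(self, tmp_path):
        cfg = SimulationConfig(design="univariate", n=150, m=300, h2=0.4,
                               n_replicates=3, seed=21)
        report = run_replicates(cfg)
        out = tmp_path / "report.csv"
        report.to_csv(out)
        text = out.read_text()
        assert text.startswith("#")
        assert "mean_estimate" in text
        assert "truth" in report.summary_text()

    def test_case_control_replicates_recover_liability_heritability(self):
        cfg = SimulationConfig(
            design="case_control", n=600, m=3000, h2=0.5, prevalence=0.1,
            case_fraction=0.5, n_replicates=40, seed=22,
        )
        report = run_replicates(cfg)
        s = report.summary
        sem = s["sd_estimate"] / math.sqrt(s["n_replicates"])
        assert abs(s["mean_estimate"] - 0.5) < 3 * sem
        # spread of liability-scale estimates tracks the transformed theory SE
        assert 0.6 < s["sd_estimate"] / s["se_theory_empirical"] < 1.5
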