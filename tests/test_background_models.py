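import numpy as np
import pytest
from scipy import stats

from capture3c.background_models import (
    IntraBackground,
    NBParams,
    build_inter_background,
    build_intra_background,
    fit_nb,
    load_backgrounds,
    sample_intra_pairs,
    save_backgrounds,
)
from capture3c.bait_definition import BaitRegion
from capture3c.genomic_io import ChromSizes, GenomicInterval
from capture3c.pet_classification import BinGrid, classify_pets
from capture3c.synthetic_data import SimConfig, simulate_pets


def nb_rvs(rng, r, p, size):
    """Sample from the (r, p) parameterization used throughout the package."""
    return rng.negative_binomial(r, 1.0 - p, size=size)


def grid_search_mle(counts, r_grid, p_grid):
    """Independent oracle: exhaustive (r, p) grid search of the likelihood."""
    values, weights = np.unique(counts, return_counts=True)
    best, best_ll = None, -np.inf
    for r in r_grid:
        for p in p_grid:
            ll = weights @ stats.nbinom.logpmf(values, r, 1.0 - p)
            if ll > best_ll:
                best, best_ll = (r, p), ll
    return best, best_ll


class TestNBParams:
    @pytest.mark.parametrize("r,p", [(2.0, 0.4), (0.5, 0.9), (10.0, 0.05)])
    def test_moment_identities(self, r, p):
        m = NBParams(r, p, "mle", 100)
        assert m.mean == pytest.approx(r * p / (1 - p))
        assert m.variance == pytest.approx(r * p / (1 - p) ** 2)
        assert m.var_mean_ratio == pytest.approx(1 / (1 - p))
        assert m.var_mean_ratio > 1

    @pytest.mark.parametrize("r,p", [(2.0, 0.4), (1.0, 0.5), (7.3, 0.12), (0.4, 0.95)])
    def test_pmf_sums_to_one(self, r, p):
        m = NBParams(r, p, "mle", 100)
        upper = int(stats.nbinom(r, 1 - p).ppf(1 - 1e-12)) + 1
        assert float(np.sum(m.pmf(np.arange(upper + 1)))) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NBParams(-1.0, 0.4, "mle", 10)
        with pytest.raises(ValueError):
            NBParams(2.0, 1.5, "mle", 10)

    def test_serialization_round_trip(self):
        m = NBParams(2.5, 0.33, "mle", 1234)
        assert NBParams.from_dict(m.to_dict()) == m


class TestFitNB:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        counts = nb_rvs(rng, 2.0, 0.4, 100_000)
        fit = fit_nb(counts)
        assert fit.fit_method == "mle"
        assert abs(fit.r - 2.0) / 2.0 < 0.05
        assert abs(fit.p - 0.4) / 0.4 < 0.05

    def test_beats_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        counts = nb_rvs(rng, 2.0, 0.4, 20_000)
        fit = fit_nb(counts)
        (r_g, p_g), ll_grid = grid_search_mle(
            counts, np.linspace(1.0, 4.0, 61), np.linspace(0.2, 0.6, 81)
        )
        values, weights = np.unique(counts, return_counts=True)
        ll_fit = weights @ stats.nbinom.logpmf(values, fit.r, 1.0 - fit.p)
        assert ll_fit >= ll_grid - 1e-6
        assert abs(fit.r - r_g) < 0.1 and abs(fit.p - p_g) < 0.02

    def test_mle_improves_on_moments_and_converges(self):
        rng = np.random.default_rng(3)
        errors = []
        for n in (1_000, 10_000, 100_000):
            counts = nb_rvs(rng, 2.0, 0.4, n)
            fit = fit_nb(counts)
            mean, var = counts.mean(), counts.var(ddof=1)
            p0 = 1 - mean / var
            r0 = mean * (1 - p0) / p0
            values, weights = np.unique(counts, return_counts=True)
            ll_mle = weights @ stats.nbinom.logpmf(values, fit.r, 1 - fit.p)
            ll_mom = weights @ stats.nbinom.logpmf(values, r0, 1 - p0)
            assert ll_mle >= ll_mom - 1e-9
            errors.append(abs(fit.r - 2.0))
        assert errors[-1] < errors[0]
        assert errors[-1] / 2.0 < 0.05

    def test_all_zero_degenerate(self):
        fit = fit_nb(np.zeros(100, dtype=int))
        assert fit.degenerate
        assert float(fit.cdf(0)) == 1.0

    def test_underdispersed_poisson_fallback(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(0.2, size=5_000)  # var ~= mean
        fit = fit_nb(counts)
        assert fit.fit_method in ("poisson_fallback", "mle")
        if fit.fit_method == "poisson_fallback":
            assert fit.mean == pytest.approx(counts.mean())
            assert fit.var_mean_ratio == 1.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            fit_nb([1, 2, 3])

    def test_overdispersion_identity_on_fit(self):
        rng = np.random.default_rng(21)
        fit = fit_nb(nb_rvs(rng, 3.0, 0.3, 50_000))
        assert fit.var_mean_ratio == pytest.approx(1 / (1 - fit.p))
        assert fit.var_mean_ratio > 1

    def test_cdf_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r = float(rng.uniform(0.2, 10.0))
            p = float(rng.uniform(0.05, 0.95))
            x = int(rng.integers(0, 40))
            m = NBParams(r, p, "mle", 1)
            brute = float(np.sum(m.pmf(np.arange(x + 1))))
            assert float(m.cdf(x)) == pytest.approx(brute, abs=1e-9)


@pytest.fixture
def sim_background(bait, sizes):
    """Simulation with known NB truth per distance stratum."""
    config = SimConfig(seed=101, n_pets=200)
    pets, truth = simulate_pets(config)
    classified, _ = classify_pets(pets, bait)
    grid = BinGrid(sizes, bait)
    return config, classified, grid


class TestSampleIntraPairs:
    def test_zero_background_all_zero(self, bait, sizes):
        grid = BinGrid(sizes, bait)
        counts = sample_intra_pairs([], grid, d=1, n=500, rng=np.random.default_rng(0))
        assert len(counts) == 500 and (counts == 0).all()

    def test_seed_determinism(self, sim_background):
        _, pets, grid = sim_background
        a = sample_intra_pairs(pets, grid, d=2, n=2000, rng=np.random.default_rng(7))
        b = sample_intra_pairs(pets, grid, d=2, n=2000, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_mean_recovers_truth(self, sim_background):
        config, pets, grid = sim_background
        rng = np.random.default_rng(1)
        for d in (1, 3):
            r, p = config.intra_truth[d]
            mu = r * p / (1 - p)
            var = r * p / (1 - p) ** 2
            counts = sample_intra_pairs(pets, grid, d=d, n=10_000, rng=rng)
            se = np.sqrt(var / len(counts))
            assert abs(counts.mean() - mu) < 4 * se + 0.02

    def test_no_candidates_returns_empty(self, bait):
        tiny = ChromSizes({"chr1": 10_000_000})
        grid = BinGrid(tiny, bait)
        counts = sample_intra_pairs([], grid, d=5000, n=100, rng=np.random.default_rng(0))
        assert len(counts) == 0


class TestBuildIntraBackground:
    def test_stratum_layout_for_2500bp_bait(self, sim_background):
        _, pets, grid = sim_background
        bg = build_intra_background(pets, grid, seed=13, n=2000, max_pooled_d=40)
        # 8 * 2500 = 20000 <= cutoff (inclusive): strata d = 1..8
        assert sorted(bg.per_d) == list(range(1, 9))
        assert bg.model_for(9) is bg.pooled
        assert bg.model_for(8) is bg.per_d[8]

    def test_decaying_means_recovered(self, sim_background):
        config, pets, grid = sim_background
        bg = build_intra_background(pets, grid, seed=13, n=10_000, max_pooled_d=40)
        ds = sorted(bg.per_d)
        means = [bg.per_d[d].mean for d in ds]
        rho = stats.spearmanr(ds, means).statistic
        assert rho < 0

    def test_parameter_recovery_within_10pct(self, sim_background):
        config, pets, grid = sim_background
        bg = build_intra_background(pets, grid, seed=13, n=10_000, max_pooled_d=40)
        for d in (1, 2):
            r, p = config.intra_truth[d]
            mu_true = r * p / (1 - p)
            assert abs(bg.per_d[d].mean - mu_true) / mu_true < 0.10

    def test_identical_truth_all_strata_agree(self, bait, sizes):
        # same NB at every separation: per-d and pooled fits should agree
        truth = {d: (2.0, 0.2) for d in range(1, 9)}
        config = SimConfig(
            seed=77, n_pets=100, intra_truth=truth,
            pooled_truth=(2.0, 0.2), pooled_d_range=(9, 20),
        )
        pets, _ = simulate_pets(config)
        classified, _ = classify_pets(pets, bait)
        grid = BinGrid(sizes, bait)
        bg = build_intra_background(classified, grid, seed=5, n=10_000, max_pooled_d=20)
        mu = 2.0 * 0.2 / 0.8
        for d, model in bg.per_d.items():
            assert model.mean == pytest.approx(mu, rel=0.15)
        assert bg.pooled.mean == pytest.approx(mu, rel=0.15)

    def test_mean_variance_relationship(self, sim_background):
        # across strata: fitted variances grow with means, superlinearly
        _, pets, grid = sim_background
        bg = build_intra_background(pets, grid, seed=13, n=10_000, max_pooled_d=40)
        means = np.array([m.mean for m in bg.per_d.values()])
        variances = np.array([m.variance for m in bg.per_d.values()])
        slope, _, rvalue, _, _ = stats.linregress(means, variances)
        assert slope > 1.0
        assert rvalue**2 > 0.9

    def test_serialization_round_trip(self, sim_background, tmp_path, sizes):
        _, pets, grid = sim_background
        intra = build_intra_background(pets, grid, seed=13, n=2000, max_pooled_d=40)
        inter = build_inter_background(pets, sizes, grid, seed=13, n=2000)
        path = str(tmp_path / "bg.json")
        save_backgrounds(intra, inter, path)
        intra2, inter2 = load_backgrounds(path)
        assert intra2.per_d == intra.per_d
        assert intra2.pooled == intra.pooled
        assert inter2.models == inter.models


class TestBuildInterBackground:
    def test_zero_trans_degenerate(self, bait, sizes):
        grid = BinGrid(sizes, bait)
        bg = build_inter_background([], sizes, grid, seed=1, n=500)
        assert set(bg.models) == {"chr2", "chr3"}
        assert all(m.degenerate for m in bg.models.values())

    def test_rate_ordering_recovered(self, bait, sizes):
        config = SimConfig(
            seed=19, n_pets=100, intra_truth={}, pooled_d_range=(9, 9),
            inter_noise_rate={"chr2": 200.0, "chr3": 2000.0},
        )
        pets, _ = simulate_pets(config)
        classified, _ = classify_pets(pets, bait)
        grid = BinGrid(sizes, bait)
        bg = build_inter_background(classified, sizes, grid, seed=4, n=10_000)
        assert bg.models["chr3"].mean > bg.models["chr2"].mean

    def test_seed_reproducibility(self, bait, sizes):
        config = SimConfig(seed=19, n_pets=100)
        pets, _ = simulate_pets(config)
        classified, _ = classify_pets(pets, bait)
        grid = BinGrid(sizes, bait)
        a = build_inter_background(classified, sizes, grid, seed=4, n=3000)
        b = build_inter_background(classified, sizes, grid, seed=4, n=3000)
        assert a.models == b.models

    def test_single_chromosome_rejected(self, bait):
        solo = ChromSizes({"chr1": 10_000_000})
        grid = BinGrid(solo, BaitRegion(GenomicInterval("chr1", 5_000_000, 5_002_500), 5_001_000, "fixed"))
        with pytest.raises(ValueError, match="2 chromosomes"):
            build_inter_background([], solo, grid, seed=0)
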