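import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slgcfate.data_model import ACD, DIFF
from slgcfate.measurements import DEFAULT_ALLOMETRY
from slgcfate.simulator import (
    ConfigurationError,
    ModelSpec,
    MotherState,
    SimCell,
    decide_fate,
    degrade_spch,
    divide_mother,
    fit_input_distributions,
    fit_truncated_beta,
    init_mothers,
    model_spec_from_dict,
    model_spec_to_dict,
    run_simulation,
    sim_inputs_from_dict,
    sim_inputs_to_dict,
)
from slgcfate.simulator import InsufficientDataError


def neighbour_model(coef=-0.8, intercept=0.8):
    return ModelSpec(
        model_id="nb",
        degradation_mode="neighbour",
        features=("neighbours",),
        intercept=intercept,
        coefficients={"neighbours": coef},
    )


class TestFitInputDistributions:
    def test_gamma_shape_recovered(self, clean_truth):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 40.0, 2000)
        shape, _, scale = stats.gamma.fit(x, floc=0)
        assert abs(shape - 2.0) / 2.0 < 0.10

    def test_poisson_mle_is_sample_mean(self, clean_cohort):
        inputs = fit_input_distributions(clean_cohort.latent)
        for ind, grp in clean_cohort.latent.groupby("individual"):
            assert inputs.individuals[ind].poisson_mean == pytest.approx(
                grp["mother_n_sig"].mean()
            )

    def test_truncated_beta_mle_recovers_shapes(self):
        rng = np.random.default_rng(3)
        raw = rng.beta(5.0, 12.0, 20000)
        kept = raw[raw < 0.5][:8000]
        a, b = fit_truncated_beta(kept)
        assert abs(a - 5.0) / 5.0 < 0.10
        assert abs(b - 12.0) / 12.0 < 0.10

    def test_loop_closure_on_clean_cohort(self, clean_truth):
        """Distributions drawn by the generator are recovered within
        sampling error when the asymmetry noise factor is off."""
        from slgcfate.synthetic import generate_cohort

        cohort = generate_cohort(clean_truth, n_individuals=1, n_cells=4000, seed=23)
        inputs = fit_input_distributions(cohort.latent)
        ind = inputs.individuals["ind1"]
        t = clean_truth
        n = 4000
        # moment-based parameters: 3 standard errors
        assert abs(ind.spch_mean - t.spch_mean) < 3 * t.spch_sd / np.sqrt(n)
        assert abs(ind.spch_sd - t.spch_sd) < 3 * t.spch_sd / np.sqrt(2 * n)
        assert abs(ind.poisson_mean - t.poisson_mean) < 3 * np.sqrt(t.poisson_mean / n)
        for cls, truth_mean in ((1, t.lam_mean_class1), (2, t.lam_mean_class2)):
            n_cls = (np.minimum(cohort.latent["n_sig_neighbours"], 2) == cls).sum()
            se = truth_mean / np.sqrt(n_cls)
            assert abs(ind.lam_mean_by_class[cls] - truth_mean) < 3 * se
        # likelihood-based shapes: generous relative tolerance at this n
        assert abs(ind.gamma_shape - t.gamma_shape) / t.gamma_shape < 0.10
        assert abs(ind.gamma_scale - t.gamma_scale) / t.gamma_scale < 0.10
        assert abs(ind.beta_a - t.beta_a) / t.beta_a < 0.15
        assert abs(ind.beta_b - t.beta_b) / t.beta_b < 0.15

    def test_too_few_cells_raises(self, clean_cohort):
        with pytest.raises(InsufficientDataError, match="cells"):
            fit_input_distributions(clean_cohort.latent.head(10))

    def test_too_few_decays_names_class(self, clean_cohort):
        lat = clean_cohort.latent.copy()
        # push everything into neighbour class 1
        lat["n_sig_neighbours"] = 1
        with pytest.raises(InsufficientDataError, match="2\\+"):
            fit_input_distributions(lat)


class TestInitMothers:
    def test_reproducible_integer_sizes(self, clean_truth):
        ind = clean_truth.individual_inputs()
        a = init_mothers(ind, "i", n=500, rng=np.random.default_rng(5))
        b = init_mothers(ind, "i", n=500, rng=np.random.default_rng(5))
        assert a == b
        sizes = np.array([m.size for m in a])
        assert np.all(sizes >= 1)
        assert np.all(sizes == sizes.astype(int))
        assert all(m.intensity >= 0 for m in a)

    def test_mean_size_within_sampling_error(self, clean_truth):
        ind = clean_truth.individual_inputs()
        mothers = init_mothers(ind, "i", n=2000, rng=np.random.default_rng(6))
        sizes = np.array([m.size for m in mothers])
        mean = ind.gamma_shape * ind.gamma_scale
        sd = np.sqrt(ind.gamma_shape) * ind.gamma_scale
        assert abs(sizes.mean() - mean) < 3 * sd / np.sqrt(2000)


class TestDivideMother:
    def test_division_arithmetic(self, clean_truth, scripted_rng):
        mother = MotherState("i", size=100, intensity=90.0, n_sig_neighbours=1)
        slgc = divide_mother(
            mother, clean_truth.individual_inputs(), scripted_rng(beta=0.4),
            noise_mode="off",
        )
        assert slgc.size == 60  # a = 0.4 -> SLGC keeps 60%
        assert slgc.meristemoid_size == 40
        assert slgc.intensity_birth == pytest.approx(60.0)  # 2/3 of 90
        assert slgc.n_sig_neighbours == 2  # mother's 1 + sister meristemoid
        assert slgc.asymmetry == 0.4

    def test_multiplicative_noise_factor_applied(self, clean_truth, scripted_rng):
        mother = MotherState("i", size=100, intensity=90.0, n_sig_neighbours=0)
        slgc = divide_mother(
            mother, clean_truth.individual_inputs(),
            scripted_rng(beta=0.4, uniform=0.75),
        )
        assert slgc.asymmetry == pytest.approx(0.3)

    def test_out_of_range_asymmetry_exhausts_rejection(self, clean_truth, scripted_rng):
        # scripted beta always 0.6 > 0.5 with noise off -> rejection loop fails
        with pytest.raises(ConfigurationError, match="rejection"):
            divide_mother(
                MotherState("i", 100, 90.0, 0),
                clean_truth.individual_inputs(),
                scripted_rng(beta=0.6),
                noise_mode="off",
            )

    def test_asymmetries_stay_in_support(self, clean_truth):
        ind = clean_truth.individual_inputs()
        rng = np.random.default_rng(9)
        for mode in ("multiplicative", "additive", "off"):
            for _ in range(200):
                slgc = divide_mother(
                    MotherState("i", 80, 60.0, 1), ind, rng, noise_mode=mode
                )
                assert 0.0 < slgc.asymmetry < 0.5
                assert 1 <= slgc.size <= 79
                assert slgc.size + slgc.meristemoid_size == 80


class TestDegradeSpch:
    def base_cell(self, size=100, nb=1):
        return SimCell(
            individual="i",
            mother_size=150,
            size=size,
            meristemoid_size=150 - size,
            asymmetry=0.33,
            nuclear_area=15.0,
            intensity_birth=60.0,
            n_sig_neighbours=nb,
        )

    def test_zero_magnitude_preserves_intensity(self, clean_truth, scripted_rng):
        cell = degrade_spch(
            self.base_cell(), "random", clean_truth.individual_inputs(),
            scripted_rng(exponential=0.0),
        )
        assert cell.lambda_per_h == 0.0
        assert cell.intensity_dip == cell.intensity_birth

    def test_size_mode_scales_per_um2_draw(self, clean_truth, scripted_rng):
        cell = degrade_spch(
            self.base_cell(size=100), "size", clean_truth.individual_inputs(),
            scripted_rng(exponential=0.002),
        )
        assert cell.lambda_per_h == pytest.approx(-0.2)
        factor = np.exp(-0.2 * 200.0 / 60.0)
        assert cell.intensity_dip == pytest.approx(60.0 * factor)
        assert factor == pytest.approx(0.513, abs=0.001)
        assert cell.conc_dip == pytest.approx(cell.intensity_dip / 15.0)

    def test_neighbour_mode_stochastic_dominance(self, clean_truth):
        ind = clean_truth.individual_inputs()
        rng = np.random.default_rng(12)
        dips = {1: [], 2: []}
        for nb in (1, 2):
            for _ in range(10_000):
                cell = degrade_spch(self.base_cell(nb=nb), "neighbour", ind, rng)
                dips[nb].append(cell.intensity_dip)
        assert np.mean(dips[2]) < np.mean(dips[1])

    def test_unknown_mode(self, clean_truth):
        with pytest.raises(ConfigurationError, match="mode"):
            degrade_spch(
                self.base_cell(), "quadratic", clean_truth.individual_inputs(),
                np.random.default_rng(0),
            )

    def test_dip_never_exceeds_birth(self, clean_truth):
        ind = clean_truth.individual_inputs()
        rng = np.random.default_rng(13)
        for mode in ("random", "neighbour", "size", "neighbour_and_size"):
            for _ in range(200):
                cell = degrade_spch(self.base_cell(), mode, ind, rng)
                assert cell.intensity_dip <= cell.intensity_birth
                assert cell.lambda_per_h <= 0


class TestDecideFate:
    def degraded_cell(self):
        from conftest import ScriptedRng
        from slgcfate.synthetic import GeneratorTruth

        cell = TestDegradeSpch().base_cell()
        return degrade_spch(
            cell, "random", GeneratorTruth().individual_inputs(),
            ScriptedRng(exponential=0.3),
        )

    def test_saturated_probabilities(self):
        cell = self.degraded_cell()
        rng = np.random.default_rng(1)
        sure = ModelSpec("p1", "random", ("size",), 1000.0, {"size": 0.0})
        never = ModelSpec("p0", "random", ("size",), -1000.0, {"size": 0.0})
        assert all(decide_fate(cell, sure, rng).fate == ACD for _ in range(50))
        assert all(decide_fate(cell, never, rng).fate == DIFF for _ in range(50))

    def test_intercept_only_bernoulli_rate(self):
        p = 0.3
        model = ModelSpec("b", "random", (), float(np.log(p / (1 - p))), {})
        cell = self.degraded_cell()
        rng = np.random.default_rng(2)
        n = 10_000
        acd = sum(decide_fate(cell, model, rng).fate == ACD for _ in range(n))
        assert abs(acd / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_interaction_terms_enter_the_logit(self):
        cell = self.degraded_cell()
        model = ModelSpec(
            "ix", "random", ("size", "neighbours"), 0.0,
            {"size": 0.0, "neighbours": 0.0, "size:neighbours": 0.01},
            interactions=(("size", "neighbours"),),
        )
        from slgcfate.simulator import fate_probability
        from scipy.special import expit

        expected = expit(0.01 * cell.size * cell.n_sig_neighbours)
        assert fate_probability(cell, model) == pytest.approx(expected)

    def test_model_spec_validation(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("m", "random", ("size",), 0.0, {"conc_dip": 1.0})
        with pytest.raises(ConfigurationError):
            ModelSpec("m", "bogus", ("size",), 0.0, {"size": 1.0})
        with pytest.raises(ConfigurationError):
            ModelSpec("m", "random", ("size",), np.inf, {"size": 1.0})


class TestRunSimulation:
    def test_deterministic_and_conservative(self, clean_truth):
        inputs = clean_truth.sim_inputs(2)
        model = clean_truth.fate_model()
        df1, _ = run_simulation(inputs, model, n=300, n_individuals=2, seed=31)
        df2, _ = run_simulation(inputs, model, n=300, n_individuals=2, seed=31)
        assert df1.to_csv() == df2.to_csv()
        assert (df1["size"] + df1["meristemoid_size"] == df1["mother_size"]).all()

    def test_negative_neighbour_effect_is_monotone(self, default_truth):
        inputs = default_truth.sim_inputs(4)
        df, summary = run_simulation(
            inputs, neighbour_model(), n=1000, n_individuals=4, seed=17
        )
        props = summary["prop_acd_by_neighbours"]
        assert props["1"] > props["2"] > props["3+"]

    def test_requesting_too_many_individuals(self, default_truth):
        with pytest.raises(ConfigurationError):
            run_simulation(
                default_truth.sim_inputs(2), neighbour_model(), n=10, n_individuals=3
            )


def test_inputs_and_model_json_round_trip(clean_truth):
    inputs = clean_truth.sim_inputs(2)
    back = sim_inputs_from_dict(sim_inputs_to_dict(inputs))
    assert back.individuals == inputs.individuals
    assert back.allometry == inputs.allometry
    model = ModelSpec(
        "full", "neighbour", ("size", "conc_dip"), 0.1,
        {"size": -0.02, "conc_dip": 1.0, "size:conc_dip": 0.001},
        interactions=(("size", "conc_dip"),),
    )
    assert model_spec_from_dict(model_spec_to_dict(model)) == model
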