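"""Stochastic lineage-fate model for stomatal-lineage ground cells.

One generation is simulated per cell, asynchronously (cells are
independent): a mother cell is initialised from per-individual fitted
distributions, divides asymmetrically into a meristemoid and an SLGC,
the SLGC's SPCH pool decays until the post-birth nadir ("dip"), and fate
(divide again vs. differentiate) is a single Bernoulli draw from a
logistic rule on the cell's state at the dip.

Four SPCH degradation modes are supported:

``random``
    decay-constant magnitudes |λ| drawn from one exponential
    distribution fitted to all cells of the individual;
``neighbour``
    one exponential per signaling-neighbour class {1, 2+};
``size``
    per-µm² magnitudes |λ|/area drawn from one exponential, scaled by
    the cell's area;
``neighbour_and_size``
    per-µm² magnitudes with one exponential per neighbour class.

λ is always per hour and non-positive inside the simulator (magnitudes
are drawn from exponentials, which are supported on the positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_model import ACD, DIFF
from .measurements import AllometryFit, DEFAULT_ALLOMETRY, estimate_nuclear_area

__all__ = [
    "DEGRADATION_MODES",
    "FATE_FEATURES",
    "IndividualInputs",
    "SimInputs",
    "ModelSpec",
    "MotherState",
    "SimCell",
    "ConfigurationError",
    "fit_input_distributions",
    "fit_truncated_beta",
    "init_mothers",
    "divide_mother",
    "degrade_spch",
    "decide_fate",
    "run_simulation",
    "sim_cells_to_frame",
    "divided_proportions",
    "NEIGHBOUR_BINS",
]

DEGRADATION_MODES = ("random", "neighbour", "size", "neighbour_and_size")
FATE_FEATURES = ("size", "conc_dip", "neighbours")
NEIGHBOUR_BINS = ("1", "2", "3+")

#: Fraction of the mother's SPCH intensity inherited by the SLGC.
SPCH_INHERITANCE = 2.0 / 3.0
#: Minutes from birth to the SPCH nadir at which fate is read out.
DEFAULT_T_DIP_MIN = 200.0

_MAX_ASYMMETRY_DRAWS = 10_000


class ConfigurationError(ValueError):
    """Distribution or model configuration that cannot produce valid draws."""


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested input distribution."""


@dataclass(frozen=True)
class IndividualInputs:
    """Fitted input distributions for one plant.

    Mother birth sizes are gamma(shape, scale) in µm², mother SPCH
    intensities normal(mean, sd) in a.u., mother signaling-neighbour
    counts Poisson(mean).  The division asymmetry a = 1 - SLGC/mother is
    beta(a, b) truncated to (0, 0.5).  Decay-constant magnitudes are
    summarised by their means (the exponential MLE): pooled and per
    neighbour class {1, 2+}, on the per-hour and per-hour-per-µm² scales.
    """

    gamma_shape: float
    gamma_scale: float
    spch_mean: float
    spch_sd: float
    poisson_mean: float
    beta_a: float
    beta_b: float
    lam_mean_all: float
    lam_mean_by_class: Mapping[int, float]
    lam_per_um2_mean_all: float
    lam_per_um2_mean_by_class: Mapping[int, float]

    def validate(self) -> None:
        for name in ("gamma_shape", "gamma_scale", "spch_sd", "poisson_mean",
                     "beta_a", "beta_b", "lam_mean_all", "lam_per_um2_mean_all"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for m in (self.lam_mean_by_class, self.lam_per_um2_mean_by_class):
            if set(m) != {1, 2} or any(v <= 0 for v in m.values()):
                raise ConfigurationError(
                    "per-class decay means must be positive and keyed {1, 2}"
                )


@dataclass(frozen=True)
class SimInputs:
    """Per-individual input distributions plus the shared allometric map."""

    individuals: Mapping[str, IndividualInputs]
    allometry: AllometryFit = DEFAULT_ALLOMETRY

    def validate(self) -> None:
        if not self.individuals:
            raise ConfigurationError("SimInputs needs at least one individual")
        for ind in self.individuals.values():
            ind.validate()


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a degradation mode plus a logistic fate rule.

    ``coefficients`` maps each included term to its logistic coefficient;
    interaction terms are keyed ``"a:b"``.  ``k`` counts every
    non-intercept coefficient (interactions included).
    """

    model_id: str
    degradation_mode: str
    features: tuple[str, ...]
    intercept: float
    coefficients: Mapping[str, float]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.degradation_mode not in DEGRADATION_MODES:
            raise ConfigurationError(
                f"unknown degradation mode {self.degradation_mode!r}; "
                f"expected one of {DEGRADATION_MODES}"
            )
        unknown = set(self.features) - set(FATE_FEATURES)
        if unknown:
            raise ConfigurationError(f"unknown fate feature(s): {sorted(unknown)}")
        expected = set(self.features) | {f"{a}:{b}" for a, b in self.interactions}
        if expected != set(self.coefficients):
            raise ConfigurationError(
                f"coefficients {sorted(self.coefficients)} do not match "
                f"terms {sorted(expected)}"
            )
        values = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("logistic coefficients must be finite")

    @property
    def k(self) -> int:
        """Non-intercept parameter count (AICc penalty); 0 = intercept-only."""
        return len(self.features) + len(self.interactions)


@dataclass(frozen=True)
class MotherState:
    """A mother cell immediately before its asymmetric division."""

    individual: str
    size: int  # µm², rounded to the nearest integer
    intensity: float  # SPCH, a.u.
    n_sig_neighbours: int


@dataclass(frozen=True)
class SimCell:
    """One simulated SLGC, tracked from birth through fate determination."""

    individual: str
    mother_size: int
    size: int
    meristemoid_size: int
    asymmetry: float
    nuclear_area: float
    intensity_birth: float
    n_sig_neighbours: int
    lambda_per_h: float | None = None
    intensity_dip: float | None = None
    conc_dip: float | None = None
    fate_p: float | None = None
    fate: str | None = None


# ---------------------------------------------------------------------------
# Input-distribution fitting


def fit_truncated_beta(x, upper: float = 0.5) -> tuple[float, float]:
    """MLE of beta(a, b) shape parameters from draws truncated to (0, upper).

    The log-likelihood is the beta log-density minus ``n * log(CDF(upper))``;
    it is maximised over (log a, log b) starting from method-of-moments
    values.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= upper)):
        raise ValueError(f"asymmetries must lie strictly inside (0, {upper})")
    m, v = x.mean(), x.var(ddof=1)
    common = max(m * (1 - m) / v - 1, 0.5)
    start = np.log([max(m * common, 0.1), max((1 - m) * common, 0.1)])

    def nll(log_ab):
        a, b = np.exp(log_ab)
        trunc = stats.beta.cdf(upper, a, b)
        if trunc <= 0:
            return np.inf
        return -(np.sum(stats.beta.logpdf(x, a, b)) - x.size * np.log(trunc))

    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = np.exp(res.x)
    return float(a), float(b)


REQUIRED_COHORT_COLUMNS = [
    "individual",
    "mother_area_um2",
    "mother_intensity_au",
    "mother_n_sig",
    "asymmetry",
    "birth_area_um2",
    "n_sig_neighbours",
    "lambda_per_h",
]


def fit_input_distributions(
    cohort: pd.DataFrame,
    allometry: AllometryFit = DEFAULT_ALLOMETRY,
    min_cells: int = 20,
    min_decays: int = 5,
) -> SimInputs:
    """Fit the simulator's input distributions per individual.

    ``cohort`` is a per-SLGC table carrying the mother-level quantities
    alongside each cell (columns in :data:`REQUIRED_COHORT_COLUMNS`); the
    synthetic generator emits exactly this table, and tracking data with
    mother links provides the same columns.

    Fits are maximum likelihood throughout: gamma via the standard MLE
    (location fixed at 0), normal via sample moments, Poisson via the
    sample mean, the asymmetry beta via truncated-beta MLE on (0, 0.5),
    and exponentials via the mean of |λ| over declining cells (λ < 0) —
    rising cells are excluded because an exponential is supported on the
    positives.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    individuals: dict[str, IndividualInputs] = {}
    for ind, grp in cohort.groupby("individual", sort=False):
        if len(grp) < min_cells:
            raise InsufficientDataError(
                f"individual {ind!r}: {len(grp)} cells < required {min_cells}"
            )
        shape, _, scale = stats.gamma.fit(grp["mother_area_um2"], floc=0)
        beta_a, beta_b = fit_truncated_beta(grp["asymmetry"].to_numpy())

        declining = grp[grp["lambda_per_h"] < 0]
        mag = -declining["lambda_per_h"].to_numpy()
        per_um2 = mag / declining["birth_area_um2"].to_numpy()
        cls = np.minimum(declining["n_sig_neighbours"].to_numpy(), 2)
        by_class, by_class_um2 = {}, {}
        for c in (1, 2):
            sel = cls == c
            if sel.sum() < min_decays:
                raise InsufficientDataError(
                    f"individual {ind!r}: {int(sel.sum())} declining cells in "
                    f"neighbour class {'2+' if c == 2 else '1'} < required {min_decays}"
                )
            by_class[c] = float(mag[sel].mean())
            by_class_um2[c] = float(per_um2[sel].mean())

        individuals[str(ind)] = IndividualInputs(
            gamma_shape=float(shape),
            gamma_scale=float(scale),
            spch_mean=float(grp["mother_intensity_au"].mean()),
            spch_sd=float(grp["mother_intensity_au"].std(ddof=1)),
            poisson_mean=float(grp["mother_n_sig"].mean()),
            beta_a=beta_a,
            beta_b=beta_b,
            lam_mean_all=float(mag.mean()),
            lam_mean_by_class=by_class,
            lam_per_um2_mean_all=float(per_um2.mean()),
            lam_per_um2_mean_by_class=by_class_um2,
        )
    inputs = SimInputs(individuals=individuals, allometry=allometry)
    inputs.validate()
    return inputs


# ---------------------------------------------------------------------------
# Simulation stages


def init_mothers(
    inputs: IndividualInputs,
    individual: str,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[MotherState]:
    """Draw a population of mother cells for one individual.

    Sizes are gamma draws rounded to the nearest integer µm² (floored at
    1), SPCH intensities are normal draws with negatives re-drawn, and
    signaling-neighbour counts are Poisson draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    inputs.validate()
    sizes = np.maximum(np.rint(rng.gamma(inputs.gamma_shape, inputs.gamma_scale, n)), 1)
    intensities = rng.normal(inputs.spch_mean, inputs.spch_sd, n)
    neg = intensities < 0
    while neg.any():  # SPCH intensity is a non-negative signal
        intensities[neg] = rng.normal(inputs.spch_mean, inputs.spch_sd, int(neg.sum()))
        neg = intensities < 0
    nbs = rng.poisson(inputs.poisson_mean, n)
    return [
        MotherState(
            individual=individual,
            size=int(sizes[i]),
            intensity=float(intensities[i]),
            n_sig_neighbours=int(nbs[i]),
        )
        for i in range(n)
    ]


def _draw_asymmetry(
    inputs: IndividualInputs, rng: np.random.Generator, noise_mode: str
) -> float:
    """Draw the division asymmetry a = 1 - SLGC/mother, rejected into (0, 0.5).

    The beta draw is perturbed by a uniform ±0.5 noise factor, applied
    multiplicatively by default (a * U(0.5, 1.5)); an additive variant
    (a + U(-0.5, 0.5)) is available.  Draws outside (0, 0.5) — where the
    SLGC would not be the larger daughter — are rejected and redrawn.
    """
    for _ in range(_MAX_ASYMMETRY_DRAWS):
        a = rng.beta(inputs.beta_a, inputs.beta_b)
        if noise_mode == "multiplicative":
            a *= rng.uniform(0.5, 1.5)
        elif noise_mode == "additive":
            a += rng.uniform(-0.5, 0.5)
        elif noise_mode != "off":
            raise ConfigurationError(f"unknown noise_mode {noise_mode!r}")
        if 0.0 < a < 0.5:
            return float(a)
    raise ConfigurationError(
        "asymmetry rejection sampling exceeded "
        f"{_MAX_ASYMMETRY_DRAWS} draws; check the beta parameters"
    )


def divide_mother(
    mother: MotherState,
    inputs: IndividualInputs,
    rng: np.random.Generator,
    allometry: AllometryFit = DEFAULT_ALLOMETRY,
    noise_mode: str = "multiplicative",
) -> SimCell:
    """Asymmetric division of a mother into an SLGC (returned) + meristemoid.

    The SLGC takes the fraction (1 - a) of the mother's size (rounded to
    integer µm², conservation enforced exactly: meristemoid = mother -
    SLGC), inherits two-thirds of the mother's SPCH intensity, and gains
    one signaling neighbour (its new sister meristemoid).  Nuclear area
    comes from the allometric map with residual noise on.
    """
    a = _draw_asymmetry(inputs, rng, noise_mode)
    slgc_size = int(np.rint(mother.size * (1.0 - a)))
    if mother.size >= 2:
        slgc_size = min(max(slgc_size, 1), mother.size - 1)
    else:
        slgc_size = mother.size
    nuclear = estimate_nuclear_area(slgc_size, allometry, noise="draw", rng=rng)
    return SimCell(
        individual=mother.individual,
        mother_size=mother.size,
        size=slgc_size,
        meristemoid_size=mother.size - slgc_size,
        asymmetry=a,
        nuclear_area=nuclear,
        intensity_birth=SPCH_INHERITANCE * mother.intensity,
        n_sig_neighbours=mother.n_sig_neighbours + 1,
    )


def degrade_spch(
    slgc: SimCell,
    mode: str,
    inputs: IndividualInputs,
    rng: np.random.Generator,
    t_dip_min: float = DEFAULT_T_DIP_MIN,
) -> SimCell:
    """Decay the SLGC's SPCH pool from birth to the dip.

    |λ| (per hour) is drawn from the mode's exponential distribution;
    per-µm² modes draw a per-µm² magnitude and scale it by the cell
    area.  λ = -|λ|, so the dip intensity never exceeds birth intensity.
    """
    if mode == "random":
        lam_mag = rng.exponential(inputs.lam_mean_all)
    elif mode == "neighbour":
        cls = min(slgc.n_sig_neighbours, 2)
        lam_mag = rng.exponential(inputs.lam_mean_by_class[cls])
    elif mode == "size":
        lam_mag = rng.exponential(inputs.lam_per_um2_mean_all) * slgc.size
    elif mode == "neighbour_and_size":
        cls = min(slgc.n_sig_neighbours, 2)
        lam_mag = rng.exponential(inputs.lam_per_um2_mean_by_class[cls]) * slgc.size
    else:
        raise ConfigurationError(
            f"unknown degradation mode {mode!r}; expected one of {DEGRADATION_MODES}"
        )
    lam = -float(lam_mag)
    intensity_dip = slgc.intensity_birth * float(np.exp(lam * t_dip_min / 60.0))
    return replace(
        slgc,
        lambda_per_h=lam,
        intensity_dip=intensity_dip,
        conc_dip=intensity_dip / slgc.nuclear_area,
    )


def _fate_feature(slgc: SimCell, name: str) -> float:
    if name == "size":
        return float(slgc.size)
    if name == "conc_dip":
        if slgc.conc_dip is None:
            raise ValueError("fate model needs conc_dip but degradation has not run")
        return float(slgc.conc_dip)
    if name == "neighbours":
        return float(slgc.n_sig_neighbours)
    raise ValueError(f"unknown fate feature {name!r}")


def fate_probability(slgc: SimCell, model: ModelSpec) -> float:
    """Logistic probability of dividing again, from the cell's dip state."""
    eta = model.intercept
    for f in model.features:
        eta += model.coefficients[f] * _fate_feature(slgc, f)
    for a, b in model.interactions:
        eta += model.coefficients[f"{a}:{b}"] * _fate_feature(slgc, a) * _fate_feature(slgc, b)
    return float(special.expit(eta))


def decide_fate(slgc: SimCell, model: ModelSpec, rng: np.random.Generator) -> SimCell:
    """One Bernoulli draw from the logistic fate rule; stores p and the fate."""
    p = fate_probability(slgc, model)
    fate = ACD if rng.random() < p else DIFF
    return replace(slgc, fate_p=p, fate=fate)


# ---------------------------------------------------------------------------
# Full runs and summaries


def sim_cells_to_frame(cells: Iterable[SimCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def neighbour_bin(n: int) -> str:
    """Bin a signaling-neighbour count into the reporting bins {1, 2, 3+}."""
    return "3+" if n >= 3 else str(int(n))


def divided_proportions(
    df: pd.DataFrame,
    bins: Sequence[str] = NEIGHBOUR_BINS,
    fate_col: str = "fate",
    nb_col: str = "n_sig_neighbours",
) -> dict[str, float]:
    """Proportion of cells that divided (ACD) per signaling-neighbour bin.

    A bin with no cells maps to NaN so that callers can decide how to
    treat it rather than receiving a silent zero.
    """
    labels = df[nb_col].map(neighbour_bin)
    out = {}
    for b in bins:
        sel = labels == b
        out[b] = float((df.loc[sel, fate_col] == ACD).mean()) if sel.any() else float("nan")
    return out


def sim_inputs_to_dict(inputs: SimInputs) -> dict:
    return {
        "allometry": {
            "alpha": inputs.allometry.alpha,
            "beta": inputs.allometry.beta,
            "sigma_eps": inputs.allometry.sigma_eps,
        },
        "individuals": {
            name: {
                **{
                    f: getattr(ind, f)
                    for f in (
                        "gamma_shape", "gamma_scale", "spch_mean", "spch_sd",
                        "poisson_mean", "beta_a", "beta_b",
                        "lam_mean_all", "lam_per_um2_mean_all",
                    )
                },
                "lam_mean_by_class": {str(k): v for k, v in ind.lam_mean_by_class.items()},
                "lam_per_um2_mean_by_class": {
                    str(k): v for k, v in ind.lam_per_um2_mean_by_class.items()
                },
            }
            for name, ind in inputs.individuals.items()
        },
    }


def sim_inputs_from_dict(d: Mapping) -> SimInputs:
    a = d.get("allometry", {})
    allometry = AllometryFit(
        alpha=a.get("alpha", DEFAULT_ALLOMETRY.alpha),
        beta=a.get("beta", DEFAULT_ALLOMETRY.beta),
        sigma_eps=a.get("sigma_eps", DEFAULT_ALLOMETRY.sigma_eps),
    )
    individuals = {}
    for name, raw in d["individuals"].items():
        raw = dict(raw)
        raw["lam_mean_by_class"] = {int(k): v for k, v in raw["lam_mean_by_class"].items()}
        raw["lam_per_um2_mean_by_class"] = {
            int(k): v for k, v in raw["lam_per_um2_mean_by_class"].items()
        }
        individuals[name] = IndividualInputs(**raw)
    inputs = SimInputs(individuals=individuals, allometry=allometry)
    inputs.validate()
    return inputs


def model_spec_to_dict(model: ModelSpec) -> dict:
    return {
        "model_id": model.model_id,
        "degradation_mode": model.degradation_mode,
        "features": list(model.features),
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "interactions": [list(pair) for pair in model.interactions],
    }


def model_spec_from_dict(d: Mapping) -> ModelSpec:
    return ModelSpec(
        model_id=d["model_id"],
        degradation_mode=d["degradation_mode"],
        features=tuple(d["features"]),
        intercept=float(d["intercept"]),
        coefficients=dict(d["coefficients"]),
        interactions=tuple(tuple(pair) for pair in d.get("interactions", [])),
    )


def run_simulation(
    inputs: SimInputs,
    model: ModelSpec,
    n: int = 1000,
    n_individuals: int = 4,
    seed: int | np.random.SeedSequence = 0,
    t_dip_min: float = DEFAULT_T_DIP_MIN,
    noise_mode: str = "multiplicative",
) -> tuple[pd.DataFrame, dict]:
    """Run one generation for ``n`` mothers in each of ``n_individuals``.

    Returns the per-SLGC table and a summary with the overall and
    per-neighbour-bin proportions that divided, and size/[SPCH]-at-dip
    moments split by fate.
    """
    inputs.validate()
    names = list(inputs.individuals)
    if n_individuals > len(names):
        raise ConfigurationError(
            f"requested {n_individuals} individuals but inputs carry {len(names)}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cells: list[SimCell] = []
    for child, name in zip(ss.spawn(n_individuals), names[:n_individuals]):
        rng = np.random.default_rng(child)
        ind = inputs.individuals[name]
        for mother in init_mothers(ind, name, n=n, rng=rng):
            slgc = divide_mother(mother, ind, rng, inputs.allometry, noise_mode)
            slgc = degrade_spch(slgc, model.degradation_mode, ind, rng, t_dip_min)
            cells.append(decide_fate(slgc, model, rng))
    df = sim_cells_to_frame(cells)
    summary = {
        "model_id": model.model_id,
        "n_cells": len(df),
        "prop_acd": float((df["fate"] == ACD).mean()),
        "prop_acd_by_neighbours": divided_proportions(df),
        "by_fate": {
            fate: {
                "n": int((df["fate"] == fate).sum()),
                "size_mean": float(df.loc[df["fate"] == fate, "size"].mean()),
                "size_sd": float(df.loc[df["fate"] == fate, "size"].std(ddof=1)),
                "conc_dip_mean": float(df.loc[df["fate"] == fate, "conc_dip"].mean()),
                "conc_dip_sd": float(df.loc[df["fate"] == fate, "conc_dip"].std(ddof=1)),
            }
            for fate in (ACD, DIFF)
        },
    }
    return df, summary
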