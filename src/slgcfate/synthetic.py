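"""Synthetic cohorts with known ground truth.

Generates per-cell birth records and fluorescence trajectories with the
statistical structure the analysis assumes: gamma-distributed mother
birth sizes, normal SPCH intensities, Poisson signaling-neighbour
counts, beta-distributed division asymmetry (truncated to (0, 0.5)),
exponentially distributed decay-constant magnitudes stratified by
neighbour class, a ln-ln cell-to-nuclear-area allometry with Gaussian
residuals, and a logistic fate rule.  Every latent draw is recorded so
downstream "true" quantities never require re-simulation.

The defaults are the package's study conditions; see ``docs/methods.md``
for what they emulate and what they deliberately do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import ACD, DIFF, CellRecord, Trajectory
from .measurements import AllometryFit
from . import simulator
from .simulator import (
    IndividualInputs,
    ModelSpec,
    SimInputs,
    decide_fate,
    degrade_spch,
    divide_mother,
    init_mothers,
)

__all__ = [
    "GeneratorTruth",
    "Cohort",
    "generate_cohort",
    "generate_allometry_sample",
    "generate_trajectory",
]


@dataclass(frozen=True)
class GeneratorTruth:
    """All parameters of the synthetic cohort generator.

    Allometry: ln(nuclear area) = beta * ln(cell area) + alpha + N(0, sigma);
    the defaults are the package's built-in epidermis calibration
    (slope 0.19, intercept 1.82, residual sd 0.027).

    Mother cells: size ~ gamma(shape, scale) µm², SPCH intensity
    ~ N(mean, sd) a.u., signaling neighbours ~ Poisson(mean).

    Division: asymmetry a = 1 - SLGC/mother ~ beta(a, b) with a uniform
    ±0.5 noise factor, rejected into (0, 0.5); the SLGC inherits 2/3 of
    the mother's SPCH and one extra signaling neighbour.

    Degradation: |λ| per hour ~ exponential, with class means chosen so
    the implied mean declines sit in the 23–42 %/h range typical of SPCH
    loss after birth (pooled and per-µm² variants are carried alongside
    for the size-scaled modes).

    Fate: P(divide) = logistic(intercept + coefficients · features) on
    {size µm², [SPCH] at dip a.u./µm², signaling neighbours}.
    """

    # allometric nuclear-size map
    allometry_alpha: float = 1.82
    allometry_beta: float = 0.19
    allometry_sigma: float = 0.027
    ln_area_range: tuple[float, float] = (2.5, 5.5)
    # mother state distributions
    gamma_shape: float = 8.0
    gamma_scale: float = 12.5  # mother sizes: mean 100 µm², sd ~35
    spch_mean: float = 100.0
    spch_sd: float = 25.0
    poisson_mean: float = 0.8  # SLGCs then carry 1..3+ signaling neighbours
    # division asymmetry
    beta_a: float = 5.0
    beta_b: float = 12.0  # mean a ~0.29, essentially all mass below 0.5
    noise_mode: str = "multiplicative"
    # SPCH degradation (|lambda| per hour)
    degradation_mode: str = "neighbour"
    lam_mean_class1: float = 0.26
    lam_mean_class2: float = 0.55
    lam_mean_all: float = 0.40
    lam_per_um2_mean_class1: float = 0.004
    lam_per_um2_mean_class2: float = 0.008
    lam_per_um2_mean_all: float = 0.006
    t_dip_min: float = 200.0
    # logistic fate rule
    fate_intercept: float = 0.4
    fate_coefficients: dict = field(
        default_factory=lambda: {"size": -0.02, "conc_dip": 1.0, "neighbours": -0.5}
    )
    # trajectory emission
    dt_min: float = 40.0
    traj_duration_min: float = 480.0
    noise_cv: float = 0.10
    bleach_pct_per_h: float = 1.8

    def validate(self) -> None:
        positive = (
            "allometry_sigma gamma_shape gamma_scale spch_sd poisson_mean beta_a "
            "beta_b lam_mean_class1 lam_mean_class2 lam_mean_all "
            "lam_per_um2_mean_class1 lam_per_um2_mean_class2 lam_per_um2_mean_all "
            "dt_min traj_duration_min"
        ).split()
        for name in positive:
            v = getattr(self, name)
            if name == "allometry_sigma":
                if v < 0:
                    raise ValueError("allometry_sigma must be >= 0")
            elif not v > 0:
                raise ValueError(f"{name} must be > 0")
        coefs = [self.fate_intercept, *self.fate_coefficients.values()]
        if not np.all(np.isfinite(coefs)):
            raise ValueError("fate coefficients must be finite")

    @property
    def allometry(self) -> AllometryFit:
        return AllometryFit(
            alpha=self.allometry_alpha,
            beta=self.allometry_beta,
            sigma_eps=self.allometry_sigma,
        )

    def individual_inputs(self) -> IndividualInputs:
        return IndividualInputs(
            gamma_shape=self.gamma_shape,
            gamma_scale=self.gamma_scale,
            spch_mean=self.spch_mean,
            spch_sd=self.spch_sd,
            poisson_mean=self.poisson_mean,
            beta_a=self.beta_a,
            beta_b=self.beta_b,
            lam_mean_all=self.lam_mean_all,
            lam_mean_by_class={1: self.lam_mean_class1, 2: self.lam_mean_class2},
            lam_per_um2_mean_all=self.lam_per_um2_mean_all,
            lam_per_um2_mean_by_class={
                1: self.lam_per_um2_mean_class1,
                2: self.lam_per_um2_mean_class2,
            },
        )

    def sim_inputs(self, n_individuals: int = 4) -> SimInputs:
        """Identical inputs for each individual (between-plant variation
        is not emulated by default)."""
        ind = self.individual_inputs()
        return SimInputs(
            individuals={f"ind{i + 1}": ind for i in range(n_individuals)},
            allometry=self.allometry,
        )

    def fate_model(self, model_id: str = "truth") -> ModelSpec:
        return ModelSpec(
            model_id=model_id,
            degradation_mode=self.degradation_mode,
            features=tuple(self.fate_coefficients),
            intercept=self.fate_intercept,
            coefficients=dict(self.fate_coefficients),
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """A generated cohort: observable tables plus the latent truth."""

    cells: list[CellRecord]
    trajectories: list[Trajectory]
    latent: pd.DataFrame
    truth: GeneratorTruth


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * s**2, s, size))


def generate_trajectory(
    n0: float,
    lambda_per_h: float,
    duration_min: float = 480.0,
    dt_min: float = 40.0,
    noise_cv: float = 0.10,
    rng: np.random.Generator | int | None = None,
    bleach_pct_per_h: float = 0.0,
    cell_id: str = "cell",
    nuclear_area_um2: float | None = None,
) -> Trajectory:
    """One fluorescence trajectory: N(t) = N0 e^{λ t}, λ per hour, t minutes.

    Sampled at {0, dt, 2dt, ...} up to ``duration_min``; measurement
    noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` (mean-corrected, so the per-timepoint expectation is the
    noiseless curve).  Photobleaching enters as a separate deterministic
    exponential factor at ``bleach_pct_per_h`` percent signal loss per
    hour.  A duration shorter than dt yields a flagged (warned)
    single-sample trajectory, not an error.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    times = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    if times.size == 1:
        warnings.warn(
            f"{cell_id}: duration {duration_min} min < sampling interval; "
            "single-sample trajectory",
            stacklevel=2,
        )
    hours = times / 60.0
    expected = n0 * np.exp(lambda_per_h * hours)
    if bleach_pct_per_h:
        expected = expected * np.exp(-(bleach_pct_per_h / 100.0) * hours)
    intensities = expected * _lognormal_noise(rng, noise_cv, times.size)
    area = None
    if nuclear_area_um2 is not None:
        area = np.full(times.size, float(nuclear_area_um2))
    return Trajectory(
        cell_id=cell_id, times=times, intensities=intensities, nuclear_area_um2=area
    )


def generate_allometry_sample(
    n: int,
    alpha: float = 1.82,
    beta: float = 0.19,
    sigma_eps: float = 0.027,
    ln_area_range: tuple[float, float] = (2.5, 5.5),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (cell area, nuclear area) draws from the allometric model.

    ln(cell areas) are uniform on ``ln_area_range``; ln(nuclear areas)
    follow the linear model with Gaussian residuals of scale
    ``sigma_eps``.  Areas are returned on the natural (µm²) scale.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    lo, hi = ln_area_range
    if hi <= lo:
        raise ValueError(f"degenerate ln_area_range {ln_area_range}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ln_cell = rng.uniform(lo, hi, n)
    eps = rng.normal(0.0, sigma_eps, n) if sigma_eps > 0 else np.zeros(n)
    ln_nuc = beta * ln_cell + alpha + eps
    return np.exp(ln_cell), np.exp(ln_nuc)


def generate_cohort(
    truth: GeneratorTruth | None = None,
    n_individuals: int = 4,
    n_cells: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> Cohort:
    """Generate a full synthetic cohort with known latent truth.

    Per individual: draw mother states, apply the asymmetric-division
    rule, draw a decay constant under the truth's degradation mode,
    propagate SPCH to the dip, assign a behaviour by one Bernoulli draw
    from the logistic fate rule, and emit a noisy trajectory per SLGC.

    Returns observable :class:`CellRecord` and :class:`Trajectory`
    collections plus a latent table with one row per SLGC holding every
    drawn quantity (mother state, asymmetry, λ, dip state, fate
    probability) — sufficient for any downstream "true" value.
    """
    truth = GeneratorTruth() if truth is None else truth
    truth.validate()
    if n_individuals < 1 or n_cells < 1:
        raise ValueError("n_individuals and n_cells must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ind_inputs = truth.individual_inputs()
    model = truth.fate_model()

    cells: list[CellRecord] = []
    trajectories: list[Trajectory] = []
    latent_rows: list[dict] = []
    for child, i in zip(ss.spawn(n_individuals), range(n_individuals)):
        rng = np.random.default_rng(child)
        name = f"ind{i + 1}"
        mothers = init_mothers(ind_inputs, name, n=n_cells, rng=rng)
        for j, mother in enumerate(mothers):
            slgc = divide_mother(
                mother, ind_inputs, rng, truth.allometry, truth.noise_mode
            )
            slgc = degrade_spch(
                slgc, truth.degradation_mode, ind_inputs, rng, truth.t_dip_min
            )
            slgc = decide_fate(slgc, model, rng)
            cell_id = f"{name}_c{j:04d}"

            # decorative geometry/position draws (no tissue simulation)
            shape_factor = rng.uniform(1.05, 1.35)
            perimeter = shape_factor * 2.0 * np.sqrt(np.pi * slgc.size)
            n_total = slgc.n_sig_neighbours + 1 + int(rng.poisson(3))
            comp = rng.multinomial(slgc.n_sig_neighbours, [0.7, 0.2, 0.1])
            contact = min(float(slgc.n_sig_neighbours * rng.uniform(0.08, 0.18)), 1.0)

            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    individual=name,
                    mother_id=f"{name}_m{j:04d}",
                    birth_time_min=float(np.round(rng.uniform(0.0, 960.0), 1)),
                    birth_area_um2=float(slgc.size),
                    perimeter_um=float(np.round(perimeter, 3)),
                    pos_x_um=float(np.round(rng.uniform(0.0, 500.0), 2)),
                    pos_y_um=float(np.round(rng.uniform(0.0, 500.0), 2)),
                    n_neighbours_total=int(n_total),
                    n_sig_neighbours=int(slgc.n_sig_neighbours),
                    n_meristemoid_nb=int(comp[0]),
                    n_gmc_nb=int(comp[1]),
                    n_stoma_nb=int(comp[2]),
                    sig_contact_fraction=float(np.round(contact, 4)),
                    behaviour=slgc.fate,
                )
            )
            trajectories.append(
                generate_trajectory(
                    n0=slgc.intensity_birth,
                    lambda_per_h=slgc.lambda_per_h,
                    duration_min=truth.traj_duration_min,
                    dt_min=truth.dt_min,
                    noise_cv=truth.noise_cv,
                    rng=rng,
                    bleach_pct_per_h=truth.bleach_pct_per_h,
                    cell_id=cell_id,
                    nuclear_area_um2=slgc.nuclear_area,
                )
            )
            latent_rows.append(
                {
                    "cell_id": cell_id,
                    "individual": name,
                    "mother_area_um2": mother.size,
                    "mother_intensity_au": mother.intensity,
                    "mother_n_sig": mother.n_sig_neighbours,
                    "asymmetry": slgc.asymmetry,
                    "birth_area_um2": float(slgc.size),
                    "birth_intensity_au": slgc.intensity_birth,
                    "n_sig_neighbours": slgc.n_sig_neighbours,
                    "nuclear_area_um2": slgc.nuclear_area,
                    "lambda_per_h": slgc.lambda_per_h,
                    "intensity_dip": slgc.intensity_dip,
                    "conc_dip": slgc.conc_dip,
                    "fate_p": slgc.fate_p,
                    "behaviour": slgc.fate,
                }
            )
    return Cohort(
        cells=cells,
        trajectories=trajectories,
        latent=pd.DataFrame(latent_rows),
        truth=truth,
    )
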