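"""Statistical evaluation and ranking of candidate simulator models.

The three-step procedure:

1. **Equivalence (TOST).** Sizes and [SPCH]-at-dip of the simulated
   dividing and differentiating populations are compared to the data's
   with two one-sided Welch tests against an equivalence bound of one
   reference-sample standard deviation; equivalence requires both
   one-sided p < 0.05.
2. **Within-population t-tests.** Welch tests for divided-vs-
   differentiated differences in size and [SPCH], run in both the
   simulation and the data; the significance patterns are compared.
3. **Error and AICc.** The sum of squared errors between simulated and
   observed proportions of cells that divided per signaling-neighbour
   bin {1, 2, 3+}, summed over individuals, enters the small-sample
   Akaike criterion AICc = N log(SSE/N) + 2(k+1) + (2k² + 2k)/(N−k−1)
   with N the number of data cells and k the number of non-intercept
   logistic fate parameters.

Steps 1–2 act as pass/fail gates and step 3 ranks the survivors
(pure-AICc ranking is available via ``gate=False``).

The module also provides the proportion-test utilities used throughout
the analysis: the two-sample proportion test with continuity
correction, the Cochran–Armitage trend test, and Holm–Bonferroni
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ACD, DIFF
from .simulator import (
    NEIGHBOUR_BINS,
    ModelSpec,
    SimInputs,
    divided_proportions,
    run_simulation,
)

__all__ = [
    "WelchResult",
    "TostResult",
    "SelectionResult",
    "welch_t_test",
    "tost_equivalence",
    "sse_by_neighbours",
    "aicc",
    "evaluate_model",
    "sweep_models",
    "two_proportion_test",
    "trend_in_proportions_test",
    "holm_adjust",
    "cohort_to_eval_frame",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def welch_t_test(x, y) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Two-sided p-value from the t distribution; no pooling of variances,
    so unequal sample sizes and variances are handled.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate test: zero variance in both samples")
    sx2, sy2 = vx / x.size, vy / y.size
    se = np.sqrt(sx2 + sy2)
    t = (x.mean() - y.mean()) / se
    df = (sx2 + sy2) ** 2 / (sx2**2 / (x.size - 1) + sy2**2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


@dataclass(frozen=True)
class TostResult:
    """Two one-sided Welch tests against an equivalence bound.

    ``equivalent`` is True iff both one-sided p-values fall below alpha;
    the bound defaults to one standard deviation of the reference
    sample.
    """

    bound: float
    t_lower: float
    p_lower: float
    t_upper: float
    p_upper: float
    df: float
    alpha: float = 0.05

    @property
    def equivalent(self) -> bool:
        return self.p_lower < self.alpha and self.p_upper < self.alpha

    @property
    def p(self) -> float:
        """The TOST p-value: the larger of the two one-sided p-values."""
        return max(self.p_lower, self.p_upper)


def tost_equivalence(reference, candidate, bound: float | None = None,
                     alpha: float = 0.05) -> TostResult:
    """TOST equivalence between a reference sample and a candidate sample.

    The null is a mean difference larger than ``bound`` in magnitude.
    When ``bound`` is None it is set to one standard deviation of the
    *reference* sample (the experimental data in model selection), so the
    bound is fixed by the reference rather than the candidate.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(candidate, dtype=float)
    if bound is None:
        bound = float(x.std(ddof=1))
    if bound < 0:
        raise ValueError("bound must be >= 0")
    base = welch_t_test(x, y)
    se = np.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
    diff = x.mean() - y.mean()
    t_lower = (diff + bound) / se  # H0: diff <= -bound
    t_upper = (diff - bound) / se  # H0: diff >= +bound
    return TostResult(
        bound=float(bound),
        t_lower=float(t_lower),
        p_lower=float(stats.t.sf(t_lower, base.df)),
        t_upper=float(t_upper),
        p_upper=float(stats.t.cdf(t_upper, base.df)),
        df=base.df,
        alpha=alpha,
    )


def sse_by_neighbours(
    sim_props: Mapping[str, float],
    data_props: Mapping[str, float],
    bins: Sequence[str] = NEIGHBOUR_BINS,
) -> float:
    """Sum over neighbour bins of (p_sim - p_data)^2."""
    total = 0.0
    for b in bins:
        for name, props in (("sim", sim_props), ("data", data_props)):
            if b not in props or not np.isfinite(props[b]):
                raise ValueError(f"{name} proportions missing bin {b!r}")
        total += (sim_props[b] - data_props[b]) ** 2
    return float(total)


def aicc(sse_total: float, n: int, k: int) -> float:
    """Small-sample corrected AIC from a total SSE.

    AICc = N ln(SSE/N) + 2(k+1) + (2k² + 2k)/(N − k − 1), natural log;
    N is the number of data cells and k the number of non-intercept
    parameters of the fate model.
    """
    if sse_total <= 0:
        raise ValueError("sse_total must be > 0")
    if n <= k + 1:
        raise ValueError(f"need N > k + 1 (got N={n}, k={k})")
    return float(
        n * np.log(sse_total / n) + 2.0 * (k + 1) + (2.0 * k**2 + 2.0 * k) / (n - k - 1)
    )


EVAL_COLUMNS = ["individual", "size", "conc_dip", "n_sig_neighbours", "fate"]


def cohort_to_eval_frame(latent: pd.DataFrame) -> pd.DataFrame:
    """Adapt a synthetic cohort's latent table to the evaluation schema."""
    return pd.DataFrame(
        {
            "individual": latent["individual"],
            "size": latent["birth_area_um2"],
            "conc_dip": latent["conc_dip"],
            "n_sig_neighbours": latent["n_sig_neighbours"],
            "fate": latent["behaviour"],
        }
    )


@dataclass
class SelectionResult:
    """Full record of one candidate model's three-step evaluation."""

    model_id: str
    k: int
    tost: dict = field(default_factory=dict)  # (fate, variable) -> TostResult|None
    tost_pass: bool = False
    welch_sim: dict = field(default_factory=dict)  # variable -> WelchResult|None
    welch_data: dict = field(default_factory=dict)
    pattern_match: bool = False
    step_failures: list = field(default_factory=list)
    sse_by_individual: dict = field(default_factory=dict)
    sse_total: float = float("nan")
    aicc: float = float("nan")
    rank: int | None = None

    @property
    def gate_pass(self) -> bool:
        return self.tost_pass and self.pattern_match and not self.step_failures


def evaluate_model(
    sim: pd.DataFrame,
    data: pd.DataFrame,
    model_id: str = "model",
    k: int = 1,
    bins: Sequence[str] = NEIGHBOUR_BINS,
    alpha: float = 0.05,
    n_data: int | None = None,
) -> SelectionResult:
    """Run the three-step evaluation of one simulated population.

    Both frames need columns ``individual, size, conc_dip,
    n_sig_neighbours, fate`` (see :func:`cohort_to_eval_frame` for the
    synthetic cohort adapter).  An empty fate class in the simulation is
    recorded as a step failure, not raised.
    """
    for frame, name in ((sim, "sim"), (data, "data")):
        missing = [c for c in EVAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} frame missing column(s): {missing}")
    res = SelectionResult(model_id=model_id, k=k)

    # Step 1: TOST equivalence of sizes and [SPCH] at dip, per fate class
    verdicts = []
    for fate in (ACD, DIFF):
        sim_f = sim[sim["fate"] == fate]
        data_f = data[data["fate"] == fate]
        for var in ("size", "conc_dip"):
            key = (fate, var)
            if len(sim_f) < 2:
                res.tost[key] = None
                res.step_failures.append(f"empty/degenerate sim fate class {fate}")
                verdicts.append(False)
                continue
            r = tost_equivalence(data_f[var], sim_f[var], alpha=alpha)
            res.tost[key] = r
            verdicts.append(r.equivalent)
    res.tost_pass = all(verdicts)

    # Step 2: divided-vs-differentiated Welch tests, sim pattern vs data pattern
    match = True
    for var in ("size", "conc_dip"):
        for frame, store in ((sim, res.welch_sim), (data, res.welch_data)):
            a = frame.loc[frame["fate"] == ACD, var]
            d = frame.loc[frame["fate"] == DIFF, var]
            try:
                store[var] = welch_t_test(a, d)
            except ValueError:
                store[var] = None
        if res.welch_sim[var] is None or res.welch_data[var] is None:
            res.step_failures.append(f"degenerate step-2 test for {var}")
            match = False
        else:
            match &= (
                res.welch_sim[var].significant == res.welch_data[var].significant
            )
    res.pattern_match = match

    # Step 3: per-individual SSE on proportions divided by neighbour bin
    sim_inds = sorted(sim["individual"].unique())
    data_inds = sorted(data["individual"].unique())
    if len(sim_inds) != len(data_inds):
        raise ValueError(
            f"individual count mismatch: sim has {len(sim_inds)}, data {len(data_inds)}"
        )
    for s_ind, d_ind in zip(sim_inds, data_inds):
        sp = divided_proportions(sim[sim["individual"] == s_ind], bins)
        dp = divided_proportions(data[data["individual"] == d_ind], bins)
        res.sse_by_individual[d_ind] = sse_by_neighbours(sp, dp, bins)
    res.sse_total = float(sum(res.sse_by_individual.values()))
    res.aicc = aicc(res.sse_total, n_data if n_data is not None else len(data), k)
    return res


def sweep_models(
    inputs: SimInputs,
    candidates: Sequence[ModelSpec],
    data: pd.DataFrame,
    seed: int | np.random.SeedSequence = 0,
    n: int = 1000,
    n_individuals: int = 4,
    gate: bool = True,
    t_dip_min: float = 200.0,
    bins: Sequence[str] = NEIGHBOUR_BINS,
) -> list[SelectionResult]:
    """Simulate and evaluate every candidate model; return them ranked.

    With ``gate=True`` candidates failing steps 1–2 rank below every
    passer; within a group the order is ascending AICc, with remaining
    ties resolved by declaration order (the sort is stable).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models to rank")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    results = []
    for child, model in zip(ss.spawn(len(candidates)), candidates):
        sim_df, _ = run_simulation(
            inputs, model, n=n, n_individuals=n_individuals, seed=child,
            t_dip_min=t_dip_min,
        )
        results.append(
            evaluate_model(sim_df, data, model_id=model.model_id, k=model.k, bins=bins)
        )
    order = sorted(
        range(len(results)),
        key=lambda i: ((0 if results[i].gate_pass else 1) if gate else 0,
                       results[i].aicc),
    )
    for rank, i in enumerate(order, start=1):
        results[i].rank = rank
    return [results[i] for i in order]


# ---------------------------------------------------------------------------
# Proportion-test utilities


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sample test for equality of proportions with continuity correction.

    Chi-squared test on the 2x2 success/failure table with the Yates
    correction (per-cell |O - E| reduced by 0.5, floored at 0), df = 1.
    Returns (chi2, p).
    """
    for k, nn in ((k1, n1), (k2, n2)):
        if nn < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= nn:
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={nn}")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = obs.sum(axis=0)
    row = obs.sum(axis=1)
    total = obs.sum()
    expected = np.outer(row, col) / total
    if np.any(expected == 0):  # all successes or all failures: no evidence
        return 0.0, 1.0
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj**2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def trend_in_proportions_test(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran–Armitage chi-squared test for trend in proportions.

    Groups are ordered; default scores are equally spaced (0, 1, 2, ...).
    Returns (chi2 with df = 1, two-sided p).  The statistic is invariant
    to reversing the group order.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.size != n.size:
        raise ValueError("successes and totals must align")
    if x.size < 3:
        raise ValueError("trend test requires >= 3 ordered groups")
    if np.any(n < 1) or np.any((x < 0) | (x > n)):
        raise ValueError("need 0 <= successes <= totals, totals >= 1")
    s = np.arange(x.size, dtype=float) if scores is None else np.asarray(scores, float)
    p_bar = x.sum() / n.sum()
    if p_bar in (0.0, 1.0):
        return 0.0, 1.0
    num = (np.sum(s * (x - n * p_bar))) ** 2
    den = p_bar * (1 - p_bar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / n.sum())
    chi2 = float(num / den)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def holm_adjust(p_values) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values.

    Adjusted values are >= the raw ones, non-decreasing in raw rank
    order, and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
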