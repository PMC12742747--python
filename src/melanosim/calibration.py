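"""Calibration of parameters against registry-style summary targets.

The simulator's likelihood is intractable, so Bayesian calibration is
performed with approximate Bayesian computation in a sequential Monte Carlo
scheme (ABC-SMC): an initial population of parameter vectors is drawn from
the priors, each is scored by a weighted squared relative error between
simulated and observed summaries, and successive generations resample and
perturb the surviving vectors under a shrinking (quantile-based) distance
threshold.  Posterior parameter uncertainty is propagated to decisions
through probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import econ
from .engine import EventType, simulate_cohort
from .mortality import STAGES

__all__ = [
    "StrataDefinition",
    "CalibrationTarget",
    "PosteriorSample",
    "CalibrationError",
    "compute_summaries",
    "second_primary_proportion",
    "distance",
    "calibrate",
    "probabilistic_sensitivity_analysis",
]

STRATUM_COLUMNS = ("age_low", "age_high", "sex", "stage")


@dataclass
class StrataDefinition:
    """Strata over which incidence and mortality rates are computed."""
    age_edges: list = field(default_factory=lambda: [15.0, 45.0, 65.0, 85.0])
    by_sex: bool = True


@dataclass
class CalibrationTarget:
    """One observed summary statistic with its stratum labels and weight."""
    statistic: str
    stratum: dict = field(default_factory=dict)
    value: float = 0.0
    weight: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError("target value must be finite")
        if self.weight <= 0:
            raise ValueError("target weight must be > 0")


@dataclass
class PosteriorSample:
    values: dict                 # parameter path -> value
    distance: float
    generation: int
    weight: float = 1.0


class CalibrationError(RuntimeError):
    """The simulation budget was exhausted before a population filled."""


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def second_primary_proportion(cohort, window: float = 10.0) -> float:
    """Among individuals with a diagnosed first primary and at least
    ``window`` years of follow-up before exit, the proportion diagnosed with
    a second primary within ``window`` years of the first diagnosis.
    NaN when the denominator is empty."""
    at_risk = 0
    hits = 0
    for h in cohort.histories:
        first = h.first_diagnosis_age
        if first is None or h.exit_age - first < window:
            continue
        at_risk += 1
        for t in h.tumours:
            if (t.tumour_index == 2 and t.diagnosed
                    and t.diagnosis_age - first <= window):
                hits += 1
                break
    return hits / at_risk if at_risk else math.nan


def compute_summaries(cohort, strata: StrataDefinition | None = None) -> pd.DataFrame:
    """Registry-style summary statistics of a simulated cohort.

    Returns one row per statistic/stratum with columns ``statistic``,
    ``age_low``, ``age_high``, ``sex``, ``stage`` and ``value``:

    * ``incidence`` - primary melanoma diagnoses (first and subsequent) per
      100,000 person-years in each age-band/sex stratum;
    * ``mortality`` - melanoma-specific deaths per 100,000 person-years;
    * ``second_primary_10y`` - 10-year second-primary proportion (NaN, i.e.
      missing, when no one is at risk);
    * ``stage_distribution`` - proportion of diagnoses by stage.

    A stratum with zero person-time reports a missing (NaN) rate, not zero.
    """
    if not cohort.histories:
        raise ValueError("cohort is empty")
    if strata is None:
        strata = StrataDefinition()
    edges = list(strata.age_edges)
    sexes = ("female", "male") if strata.by_sex else ("all",)

    person_years = {(i, s): 0.0 for i in range(len(edges) - 1) for s in sexes}
    dx_counts = {(i, s): 0 for i in range(len(edges) - 1) for s in sexes}
    death_counts = {(i, s): 0 for i in range(len(edges) - 1) for s in sexes}
    stage_counts = {s: 0 for s in STAGES}

    for h in cohort.histories:
        s = h.sex if strata.by_sex else "all"
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            overlap = min(h.exit_age, hi) - max(h.entry_age, lo)
            if overlap > 0:
                person_years[(i, s)] += overlap
        for t in h.tumours:
            if t.diagnosed:
                stage_counts[t.stage_at_diagnosis] += 1
                i = _band(edges, t.diagnosis_age)
                if i is not None:
                    dx_counts[(i, s)] += 1
        if h.exit_cause == EventType.MELANOMA_DEATH.value:
            i = _band(edges, h.exit_age)
            if i is not None:
                death_counts[(i, s)] += 1

    rows = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        for s in sexes:
            py = person_years[(i, s)]
            for stat, counts in (("incidence", dx_counts), ("mortality", death_counts)):
                value = counts[(i, s)] / py * 1e5 if py > 0 else math.nan
                rows.append({"statistic": stat, "age_low": lo, "age_high": hi,
                             "sex": s, "stage": math.nan, "value": value})
    rows.append({"statistic": "second_primary_10y", "age_low": math.nan,
                 "age_high": math.nan, "sex": math.nan, "stage": math.nan,
                 "value": second_primary_proportion(cohort)})
    total_dx = sum(stage_counts.values())
    for stage in STAGES:
        value = stage_counts[stage] / total_dx if total_dx else math.nan
        rows.append({"statistic": "stage_distribution", "age_low": math.nan,
                     "age_high": math.nan, "sex": math.nan, "stage": stage,
                     "value": value})
    return pd.DataFrame(rows)


def _band(edges, age):
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        if lo <= age < hi:
            return i
    if age == edges[-1]:
        return len(edges) - 2
    return None


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def _lookup(summaries: pd.DataFrame, target: CalibrationTarget) -> float:
    mask = summaries["statistic"] == target.statistic
    for col in STRATUM_COLUMNS:
        want = target.stratum.get(col)
        if want is None:
            mask &= summaries[col].isna()
        else:
            mask &= summaries[col] == want
    found = summaries.loc[mask, "value"]
    if len(found) != 1:
        raise KeyError(f"target {target.statistic} {target.stratum} matched "
                       f"{len(found)} summary rows (expected 1)")
    return float(found.iloc[0])


def distance(summaries: pd.DataFrame, targets: list) -> float:
    """Weighted squared relative error between simulated summaries and the
    targets; zero iff every target is matched exactly.  Relative error falls
    back to absolute error for targets whose observed value is zero; a
    missing simulated statistic counts as maximally discrepant."""
    total = 0.0
    for t in targets:
        sim = _lookup(summaries, t)
        if math.isnan(sim):
            total += t.weight * 1.0  # missing stratum in simulation
            continue
        denom = abs(t.value) if t.value != 0 else 1.0
        total += t.weight * ((sim - t.value) / denom) ** 2
    return total


# ---------------------------------------------------------------------------
# ABC-SMC
# ---------------------------------------------------------------------------

def _apply(params, values: dict):
    out = params
    for path, v in values.items():
        out = out.with_value(path, float(v))
    return out


def calibrate(params, priors: list, targets: list, *,
              n_per_draw: int = 500,
              population_size: int = 24,
              n_generations: int = 3,
              keep_fraction: float = 0.5,
              budget: int = 1000,
              seed: int = 0,
              policy=None,
              strata: StrataDefinition | None = None,
              summary_fn=None,
              history_out: list | None = None) -> list:
    """ABC-SMC posterior sampling.

    Each candidate parameter vector is applied to ``params``, a cohort of
    ``n_per_draw`` individuals is simulated (with a seed derived from
    ``seed`` so the whole run is reproducible), and the weighted distance to
    the targets is computed.  Generation 0 draws from the priors; each later
    generation resamples the survivors by weight, perturbs them with a
    Gaussian kernel (variance twice the weighted population variance), and
    accepts candidates under the previous generation's keep-quantile
    threshold.  Raises :class:`CalibrationError` if ``budget`` simulations
    are spent before a population fills.

    If ``history_out`` is a list, every generation's population (including
    generation 0) is appended to it, for convergence diagnostics.
    """
    if not priors or not targets:
        raise ValueError("calibrate requires at least one prior and one target")
    from .params import validate as validate_params

    rng = np.random.default_rng(seed)
    paths = [p.parameter_path for p in priors]
    spent = 0

    def score(values: dict) -> float:
        nonlocal spent
        if spent >= budget:
            raise CalibrationError(
                f"simulation budget {budget} exhausted (generation population "
                f"unfilled; increase budget or loosen thresholds)")
        spent += 1
        candidate = _apply(params, values)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(candidate, n_per_draw, sim_seed, policy=policy)
        if summary_fn is not None:
            summaries = summary_fn(cohort)
        else:
            summaries = compute_summaries(cohort, strata)
        return distance(summaries, targets)

    def valid(values: dict) -> bool:
        if any(not p.in_support(values[p.parameter_path]) for p in priors):
            return False
        return not validate_params(_apply(params, values))

    # generation 0: prior sampling
    population = []
    while len(population) < population_size:
        values = {p.parameter_path: p.sample(rng) for p in priors}
        if not valid(values):
            continue
        population.append(PosteriorSample(values, score(values), 0, 1.0))
    if history_out is not None:
        history_out.append(list(population))

    threshold = math.inf
    for gen in range(1, n_generations + 1):
        dists = np.array([s.distance for s in population])
        threshold = float(np.quantile(dists, keep_fraction))
        survivors = [s for s in population if s.distance <= threshold]
        weights = np.array([s.weight for s in survivors], dtype=float)
        weights /= weights.sum()
        arr = np.array([[s.values[p] for p in paths] for s in survivors])
        mean = np.average(arr, axis=0, weights=weights)
        var = np.average((arr - mean) ** 2, axis=0, weights=weights)
        kernel_sd = np.sqrt(np.maximum(2.0 * var, 1e-12))

        new_population = []
        while len(new_population) < population_size:
            pick = survivors[int(rng.choice(len(survivors), p=weights))]
            proposal = {
                path: pick.values[path] + rng.normal(0.0, kernel_sd[j])
                for j, path in enumerate(paths)
            }
            if not valid(proposal):
                continue
            d = score(proposal)
            if d > threshold:
                continue
            # importance weight: prior density over kernel mixture density
            num = np.prod([p.pdf(proposal[p.parameter_path]) for p in priors])
            mix = 0.0
            for wi, s in zip(weights, survivors):
                k = np.prod([
                    math.exp(-0.5 * ((proposal[path] - s.values[path]) / kernel_sd[j]) ** 2)
                    / (kernel_sd[j] * math.sqrt(2 * math.pi))
                    for j, path in enumerate(paths)
                ])
                mix += wi * k
            w = float(num / mix) if mix > 0 else 0.0
            new_population.append(PosteriorSample(proposal, d, gen, w))
        population = new_population
        if history_out is not None:
            history_out.append(list(population))

    return population


def posterior_interval(samples: list, path: str, level: float = 0.95):
    """Central credible interval for one parameter from a weighted ABC
    population (importance weights taken into account)."""
    values = np.array([s.values[path] for s in samples], dtype=float)
    weights = np.array([s.weight for s in samples], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) / weights.sum()
    alpha = (1.0 - level) / 2.0
    lo = values[int(np.searchsorted(cum, alpha))]
    hi = values[min(int(np.searchsorted(cum, 1.0 - alpha)), len(values) - 1)]
    return float(lo), float(hi)


def posterior_frame(samples: list) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = dict(s.values)
        row.update({"distance": s.distance, "generation": s.generation,
                    "weight": s.weight})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def probabilistic_sensitivity_analysis(samples: list, params, policy,
                                       comparator_policy=None, *,
                                       n_per_draw: int = 1000,
                                       seed: int = 0) -> pd.DataFrame:
    """Propagate posterior parameter uncertainty to incremental outcomes.

    For each posterior sample the policy and comparator cohorts are
    simulated under common random numbers, accrued at the parameter set's
    discount rate, and scored at its willingness-to-pay threshold.  The
    returned frame has one row per draw (incremental cost, QALYs, net
    monetary benefit, cost-effective indicator); its ``cost_effective``
    column's mean is the cost-effectiveness acceptability fraction at that
    threshold.
    """
    if not samples:
        raise ValueError("PSA requires a non-empty posterior")
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        candidate = _apply(params, s.values)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        strategy = simulate_cohort(candidate, n_per_draw, sim_seed, policy=policy)
        comparator = simulate_cohort(candidate, n_per_draw, sim_seed,
                                     policy=comparator_policy)
        econ_cfg = candidate.economics
        res = econ.compare(strategy, comparator, econ_cfg.tariff,
                           econ_cfg.utilities, econ_cfg.discount_rate,
                           econ_cfg.wtp_threshold)
        rows.append({
            "incremental_cost": res.incremental_cost,
            "incremental_qaly": res.incremental_qaly,
            "nmb": res.net_monetary_benefit,
            "cost_effective": res.net_monetary_benefit > 0,
        })
    return pd.DataFrame(rows)
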