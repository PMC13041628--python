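"""Monte Carlo orchestration: scenario portfolios, interval summaries, and
the rank-stability sensitivity suite.

Fixed-budget channel-mix scenarios (A-H) reuse one network pair across all
replications (variance reduction for within-block comparisons); intervention
and framing scenarios (I-O) regenerate both layers at the start of every
replication to fold in structural uncertainty. Replication r of a plan with
base seed s uses seed s + r, so variant configurations compared on the same
plan share common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from . import dynamics, metrics, networks
from .scenarios import ScenarioSpec, catalog

#: heuristic benchmarks for high rank stability
STABILITY_RHO = 0.90
STABILITY_DRANK = 1


@dataclass(frozen=True)
class ReplicationPlan:
    n_reps: int = 100
    base_seed: int = 0
    network_seed: int | None = None   # defaults to base_seed

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def net_seed(self) -> int:
        return self.base_seed if self.network_seed is None else self.network_seed


@dataclass
class ScenarioSummary:
    """Replication-level outcome summaries for one scenario."""

    scenario_id: str
    task: str
    n_reps: int
    mean_adoption: float
    adoption_pi: tuple[float, float]
    mean_tta: float | None
    tta_pi: tuple[float, float]
    mean_awareness: float
    awareness_pi: tuple[float, float]
    equity: metrics.EquityReport
    adoption_reps: np.ndarray = field(repr=False)
    tta_reps: np.ndarray = field(repr=False)
    awareness_reps: np.ndarray = field(repr=False)
    class_adoption_reps: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        eq = self.equity
        return {
            "scenario": self.scenario_id, "task": self.task,
            "n_reps": self.n_reps, "mean_adoption": self.mean_adoption,
            "adoption_pi": list(self.adoption_pi), "mean_tta": self.mean_tta,
            "tta_pi": list(self.tta_pi), "mean_awareness": self.mean_awareness,
            "a_min": eq.a_min, "gap_90_10": eq.gap_90_10, "rdi": eq.rdi,
            "theil_T": eq.theil_T, "atkinson": eq.atkinson,
            "guardrails_pass": eq.pass_all,
        }


def percentile_interval(samples, lo: float = 2.5, hi: float = 97.5
                        ) -> tuple[float, float]:
    """Empirical percentile interval, linear interpolation."""
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("need at least one sample")
    a, b = np.percentile(s, [lo, hi])
    return float(a), float(b)


def run_scenario(plan: ReplicationPlan, spec: ScenarioSpec,
                 params: dynamics.ModelParams, population,
                 network: networks.LayeredNetwork | None = None
                 ) -> ScenarioSummary:
    """Simulate one scenario for ``plan.n_reps`` replications.

    For the fixed-network policy a single network pair (built from the
    plan's network seed unless one is passed in) is reused; under the
    regenerate policy both layers are rebuilt per replication.
    """
    deg = population.degree_targets
    if not spec.regenerate_networks and network is None:
        network = networks.build_layered(deg, seed=plan.net_seed)

    adoption, tta, aware, class_adopt = [], [], [], []
    for r in range(1, plan.n_reps + 1):
        seed = plan.base_seed + r
        net = (networks.build_layered(deg, seed=plan.net_seed + r)
               if spec.regenerate_networks else network)
        res = dynamics.run_simulation(population, net, spec, params, seed)
        adoption.append(metrics.final_adoption(res))
        aware.append(metrics.awareness_rate(res))
        t = metrics.mean_time_to_adoption(res)
        tta.append(np.nan if t is None else t)
        class_adopt.append(metrics.class_adoption(res, population.modal_class))

    adoption = np.array(adoption)
    aware = np.array(aware)
    tta = np.array(tta)
    class_adopt = np.array(class_adopt)
    tta_ok = tta[~np.isnan(tta)]
    sizes = np.bincount(population.modal_class, minlength=7)[1:]
    return ScenarioSummary(
        scenario_id=spec.id, task=spec.task, n_reps=plan.n_reps,
        mean_adoption=float(adoption.mean()),
        adoption_pi=percentile_interval(adoption),
        mean_tta=float(tta_ok.mean()) if tta_ok.size else None,
        tta_pi=percentile_interval(tta_ok) if tta_ok.size else (np.nan, np.nan),
        mean_awareness=float(aware.mean()),
        awareness_pi=percentile_interval(aware),
        equity=metrics.guardrail_screen(class_adopt.mean(axis=0), sizes),
        adoption_reps=adoption, tta_reps=tta, awareness_reps=aware,
        class_adoption_reps=class_adopt)


def run_portfolio(task: str, population, params: dynamics.ModelParams,
                  plan: ReplicationPlan, scenario_ids: str | None = None,
                  delta: float = 0.02) -> dict[str, ScenarioSummary]:
    """All (or selected) scenarios for one task under a single plan, sharing
    the fixed network pair across the A-H block."""
    specs = [s for s in catalog(task, delta=delta)
             if scenario_ids is None or s.id in scenario_ids]
    fixed_net = None
    out = {}
    for spec in specs:
        if not spec.regenerate_networks and fixed_net is None:
            fixed_net = networks.build_layered(population.degree_targets,
                                               seed=plan.net_seed)
        out[spec.id] = run_scenario(plan, spec, params, population,
                                    network=fixed_net)
    return out


# ---------------------------------------------------------------------------
# sensitivity: rank stability across prespecified axes


@dataclass
class StabilityResult:
    axis: str
    spearman_rho: float
    max_rank_shift: int
    passes: bool
    baseline: dict[str, float] = field(default_factory=dict, repr=False)
    variant: dict[str, float] = field(default_factory=dict, repr=False)


def rank_stability(baseline: dict[str, float], variant: dict[str, float],
                   axis: str = "") -> StabilityResult:
    """Spearman correlation (average-rank ties) and maximum absolute rank
    shift between two scenario -> mean-adoption maps on the same key set."""
    if set(baseline) != set(variant):
        raise ValueError("scenario key sets differ")
    keys = sorted(baseline)
    b = np.array([baseline[k] for k in keys])
    v = np.array([variant[k] for k in keys])
    if np.allclose(b, b[0]) or np.allclose(v, v[0]):
        rho = 1.0 if np.allclose(b - b.mean(), v - v.mean()) else np.nan
    else:
        rho = float(spearmanr(b, v).statistic)
    shift = int(round(np.max(np.abs(rankdata(b) - rankdata(v)))))
    return StabilityResult(
        axis=axis, spearman_rho=rho, max_rank_shift=shift,
        passes=rho >= STABILITY_RHO and shift <= STABILITY_DRANK,
        baseline=dict(baseline), variant=dict(variant))


def _means(summaries: dict[str, ScenarioSummary]) -> dict[str, float]:
    return {k: s.mean_adoption for k, s in summaries.items()}


SENSITIVITY_AXES = ("link", "weight_allocation", "tau", "network_seeds")


def sensitivity_suite(task: str, population, params: dynamics.ModelParams,
                      plan: ReplicationPlan,
                      axes=SENSITIVITY_AXES,
                      baseline: dict[str, ScenarioSummary] | None = None
                      ) -> list[StabilityResult]:
    """Rerun the full 15-scenario portfolio under each sensitivity variant
    (common random numbers with the baseline) and report rank stability.

    Axes: ``link`` (logistic in place of clipped-linear); ``weight_allocation``
    (media-centric beta_m=1.5/beta_s=0.1 and social-centric 0.5/0.4);
    ``tau`` (reinforcement threshold 2 -> 1); ``network_seeds`` (alternative
    network realizations).
    """
    if baseline is None:
        baseline = run_portfolio(task, population, params, plan)
    base_means = _means(baseline)

    variants: list[tuple[str, dynamics.ModelParams, ReplicationPlan]] = []
    if "link" in axes:
        variants.append(("link:logistic", params.replace(link="logistic"), plan))
    if "weight_allocation" in axes:
        variants.append(("weight_allocation:media_centric",
                         params.replace(beta_m=1.5, beta_s=0.1), plan))
        variants.append(("weight_allocation:social_centric",
                         params.replace(beta_m=0.5, beta_s=0.4), plan))
    if "tau" in axes:
        variants.append(("tau:1", params.replace(tau=1), plan))
    if "network_seeds" in axes:
        alt = ReplicationPlan(n_reps=plan.n_reps, base_seed=plan.base_seed,
                              network_seed=plan.net_seed + 10_000)
        variants.append(("network_seeds:alternative", params, alt))

    out = []
    for axis, p, pl in variants:
        var = run_portfolio(task, population, p, pl)
        out.append(rank_stability(base_means, _means(var), axis=axis))
    return out
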