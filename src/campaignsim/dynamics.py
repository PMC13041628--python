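"""The simulation engine: monthly two-phase awareness/adoption updates.

Agents move up an absorbing three-state ladder — unaware (0), aware (1),
adopted (2) — over T=12 monthly steps. Each step first updates awareness,
then adoption conditional on awareness, visiting agents in a fresh uniform
random permutation per phase.

Awareness linear predictor for agent i:

    L_aware = W_BG + sum_c m_c * W_c(i) * a_c(i) + omega_a * f_aware(i)

where a_c is the agent's channel-use level, W_c(i) its scenario-resolved
channel weight, m_c = k_neg for TV/digital in the framing scenarios (else 1),
and f_aware the fraction of union-network neighbors that are aware or
adopted. Adoption (only for aware agents):

    L_adopt = alpha * b_step + beta_m * sum_c m_c * W_c(i) * a_c(i)
              + beta_s * 1[n_adopted >= tau] * f_adopted

with complex-contagion reinforcement active only once at least tau (=2 by
default) neighbors have adopted. Probabilities come from a clipped-linear
link (clip to [0,1]) by default, or a logistic link anchored to agree with
the clipped-linear link at L=0 and L=0.5.

Within a phase, updates are sequential by default (agents updated earlier in
the permutation are visible to later agents); a synchronous mode evaluating
all agents against the phase-start snapshot is available for sensitivity.
The hot path is a numba-compiled kernel; :func:`step` is an equivalent pure
NumPy reference used on small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .scenarios import ScenarioSpec, effective_agent_weights

# logistic-link anchoring: p(0.5)=0.5 and slope matches clipped-linear there
LOGISTIC_GAMMA0 = -2.0
LOGISTIC_GAMMA1 = 4.0

_LINKS = {"clipped_linear": 0, "logistic": 1}


@dataclass(frozen=True)
class ModelParams:
    """Behavioral parameters of the engine (defaults: calibrated vaccination
    configuration; use :func:`default_params` for per-task defaults)."""

    alpha: float = 1.15        # baseline propensity multiplier (calibrated)
    w_bg: float = 0.12         # background exposure weight (calibrated)
    omega_a: float = 0.30      # social-awareness weight
    beta_m: float = 1.0        # media weight in the adoption predictor
    beta_s: float = 0.20       # social-reinforcement weight
    tau: int = 2               # adopted-neighbor threshold for reinforcement
    link: str = "clipped_linear"
    T: int = 12                # horizon in monthly steps
    sequential: bool = True    # within-phase update order semantics
    personalization_mode: str = "posterior"

    def __post_init__(self):
        if min(self.alpha, self.w_bg, self.omega_a, self.beta_m, self.beta_s) < 0:
            raise ValueError("weights must be non-negative")
        if self.tau < 1 or self.T < 1:
            raise ValueError("tau and T must be >= 1")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


_CALIBRATED_DEFAULTS = {"vaccination": (1.15, 0.12), "screening": (1.03, 0.10)}


def default_params(task: str, **kw) -> ModelParams:
    alpha, w_bg = _CALIBRATED_DEFAULTS[task]
    return ModelParams(alpha=alpha, w_bg=w_bg, **kw)


@dataclass
class SimState:
    """Mutable simulation state (reference path)."""

    state: np.ndarray      # (N,) values 0/1/2
    t_aware: np.ndarray    # first awareness step (0 = never)
    t_adopt: np.ndarray    # first adoption step (0 = never)
    t: int = 0

    @classmethod
    def initial(cls, n: int) -> "SimState":
        return cls(state=np.zeros(n, np.int8), t_aware=np.zeros(n, np.int32),
                   t_adopt=np.zeros(n, np.int32), t=0)


@dataclass
class SimResult:
    """Per-agent awareness/adoption times for one replication."""

    t_aware: np.ndarray
    t_adopt: np.ndarray
    state: np.ndarray
    scenario_id: str
    task: str
    seed: int

    @property
    def n(self) -> int:
        return self.state.size


# ---------------------------------------------------------------------------
# probability components


def _apply_link(L, link: str):
    if link == "clipped_linear":
        return np.clip(L, 0.0, 1.0)
    return 1.0 / (1.0 + np.exp(-(LOGISTIC_GAMMA0 + LOGISTIC_GAMMA1 * np.asarray(L))))


def media_exposure(weights, a, k_neg: float = 1.0):
    """sum_c m_c * W_c * a_c with the framing multiplier on TV and digital."""
    weights = np.asarray(weights, float)
    a = np.asarray(a, float)
    m = np.array([k_neg, k_neg, 1.0])
    return (weights * a * m).sum(axis=-1)


def awareness_probability(agent, spec: ScenarioSpec, params: ModelParams,
                          frac_aware_neighbors: float) -> float:
    """Awareness probability for one agent (background + media + spillover)."""
    w = effective_agent_weights(spec, agent.class_posterior, agent.class_modal,
                                params.personalization_mode)
    k = spec.k_neg if spec.is_framing else 1.0
    L = params.w_bg + media_exposure(w, agent.a, k) \
        + params.omega_a * frac_aware_neighbors
    return float(_apply_link(L, params.link))


def adoption_probability(agent, spec: ScenarioSpec, params: ModelParams,
                         n_adopted_neighbors: int,
                         frac_adopted_neighbors: float) -> float:
    """Adoption probability for one (aware) agent: scaled baseline hazard +
    media exposure + threshold-gated social reinforcement."""
    w = effective_agent_weights(spec, agent.class_posterior, agent.class_modal,
                                params.personalization_mode)
    k = spec.k_neg if spec.is_framing else 1.0
    reinforcement = (params.beta_s * frac_adopted_neighbors
                     if n_adopted_neighbors >= params.tau else 0.0)
    L = params.alpha * agent.b_step + params.beta_m * media_exposure(w, agent.a, k) \
        + reinforcement
    return float(_apply_link(L, params.link))


def resolve_exposure_terms(population, spec: ScenarioSpec,
                           params: ModelParams) -> np.ndarray:
    """Per-agent media exposure term sum_c m_c W_c(i) a_c(i), vectorized."""
    from .scenarios import class_weight_matrix
    Wmat = class_weight_matrix(spec)  # (6, 3)
    if params.personalization_mode == "posterior":
        W = population.posterior @ Wmat
    else:
        W = Wmat[population.modal_class - 1]
    k = spec.k_neg if spec.is_framing else 1.0
    m = np.array([k, k, 1.0])
    return (W * population.a * m).sum(axis=1)


# ---------------------------------------------------------------------------
# compiled kernel (hot path)


@njit(cache=True)
def _simulate_kernel(seed, T, indptr, indices, aware_base, adopt_base,
                     omega_a, beta_s, tau, link_id, g0, g1, sequential):
    np.random.seed(seed)
    n = aware_base.size
    state = np.zeros(n, np.int8)
    t_aware = np.zeros(n, np.int32)
    t_adopt = np.zeros(n, np.int32)
    snapshot = np.zeros(n, np.int8)
    for t in range(1, T + 1):
        # phase 1: awareness
        perm = np.random.permutation(n)
        if not sequential:
            snapshot[:] = state
        ref = state if sequential else snapshot
        for idx in range(n):
            i = perm[idx]
            if state[i] != 0:
                continue
            s, e = indptr[i], indptr[i + 1]
            deg = e - s
            na = 0
            for j in range(s, e):
                if ref[indices[j]] >= 1:
                    na += 1
            frac = na / deg if deg > 0 else 0.0
            L = aware_base[i] + omega_a * frac
            if link_id == 0:
                p = min(max(L, 0.0), 1.0)
            else:
                p = 1.0 / (1.0 + np.exp(-(g0 + g1 * L)))
            if np.random.random() < p:
                state[i] = 1
                t_aware[i] = t
        # phase 2: adoption conditional on awareness
        perm = np.random.permutation(n)
        if not sequential:
            snapshot[:] = state
        ref = state if sequential else snapshot
        for idx in range(n):
            i = perm[idx]
            if state[i] != 1:
                continue
            s, e = indptr[i], indptr[i + 1]
            deg = e - s
            nad = 0
            for j in range(s, e):
                if ref[indices[j]] == 2:
                    nad += 1
            frac = nad / deg if deg > 0 else 0.0
            L = adopt_base[i]
            if nad >= tau:
                L += beta_s * frac
            if link_id == 0:
                p = min(max(L, 0.0), 1.0)
            else:
                p = 1.0 / (1.0 + np.exp(-(g0 + g1 * L)))
            if np.random.random() < p:
                state[i] = 2
                t_adopt[i] = t
    return state, t_aware, t_adopt


def run_simulation(population, net, spec: ScenarioSpec, params: ModelParams,
                   seed: int) -> SimResult:
    """One replication: T steps from an all-unaware start; deterministic
    under (seed, inputs); records each agent's first awareness/adoption step."""
    media = resolve_exposure_terms(population, spec, params)
    aware_base = params.w_bg + media
    adopt_base = params.alpha * population.b_step + params.beta_m * media
    indptr, indices = net.union_csr()
    # mix the seed so consecutive replication seeds give decorrelated streams
    kernel_seed = int(np.random.SeedSequence(int(seed)).generate_state(1)[0])
    state, t_aware, t_adopt = _simulate_kernel(
        kernel_seed % (2 ** 31), params.T, indptr, indices,
        np.ascontiguousarray(aware_base), np.ascontiguousarray(adopt_base),
        params.omega_a, params.beta_s, params.tau, _LINKS[params.link],
        LOGISTIC_GAMMA0, LOGISTIC_GAMMA1, params.sequential)
    return SimResult(t_aware=t_aware, t_adopt=t_adopt, state=state,
                     scenario_id=spec.id, task=spec.task, seed=int(seed))


# ---------------------------------------------------------------------------
# pure NumPy reference path (small problems, readable semantics)


def step(sim: SimState, population, net, spec: ScenarioSpec,
         params: ModelParams, rng: np.random.Generator) -> SimState:
    """Advance the state by one month (reference implementation; mutates and
    returns ``sim``). Distributionally identical to the compiled kernel."""
    if sim.t >= params.T:
        raise RuntimeError(f"simulation already at horizon T={params.T}")
    media = resolve_exposure_terms(population, spec, params)
    n = sim.state.size
    t = sim.t + 1
    for phase in (1, 2):
        perm = rng.permutation(n)
        ref = sim.state if params.sequential else sim.state.copy()
        for i in perm:
            if phase == 1 and sim.state[i] == 0:
                nbrs = list(net.union_neighbors(int(i)))
                frac = (np.mean(ref[nbrs] >= 1) if nbrs else 0.0)
                L = params.w_bg + media[i] + params.omega_a * frac
                if rng.random() < _apply_link(L, params.link):
                    sim.state[i] = 1
                    sim.t_aware[i] = t
            elif phase == 2 and sim.state[i] == 1:
                nbrs = list(net.union_neighbors(int(i)))
                nad = int(np.sum(ref[nbrs] == 2)) if nbrs else 0
                frac = nad / len(nbrs) if nbrs else 0.0
                L = params.alpha * population.b_step[i] + params.beta_m * media[i]
                if nad >= params.tau:
                    L += params.beta_s * frac
                if rng.random() < _apply_link(L, params.link):
                    sim.state[i] = 2
                    sim.t_adopt[i] = t
    sim.t = t
    return sim


def run_simulation_reference(population, net, spec, params, seed) -> SimResult:
    """T-step run through the pure NumPy :func:`step` path."""
    rng = np.random.default_rng(seed)
    sim = SimState.initial(population.n if hasattr(population, "n")
                           else population.b_step.size)
    for _ in range(params.T):
        step(sim, population, net, spec, params, rng)
    return SimResult(t_aware=sim.t_aware, t_adopt=sim.t_adopt, state=sim.state,
                     scenario_id=spec.id, task=spec.task, seed=int(seed))


@dataclass
class ArrayPopulation:
    """Minimal array-backed population for direct engine use (tests, small
    constructed examples)."""

    posterior: np.ndarray
    modal_class: np.ndarray
    a: np.ndarray
    b_step: np.ndarray
    degree_targets: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.b_step.size
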