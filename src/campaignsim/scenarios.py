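"""The 15 prespecified campaign scenarios (A-O).

Scenarios vary four design factors under a fixed per-step media budget:

* channel allocation (A control; B/C/D single-channel; E-H fixed-sum mixes),
* budget intensity (I scaled down, J scaled up),
* class-level personalization (K equity-focused reweighting toward the
  lowest-baseline-uptake class; L class-tailored TV/digital portfolios),
* loss framing (M/N/O: B/C/E with the TV and digital exposure terms scaled
  by a multiplier k_neg on a per-task grid).

Weights are relative per-step exposure intensities, not monetary spend.
For B-H the three channel weights sum to ~0.10; K keeps the *class-average*
TV+digital budget at exactly 0.10 for both intensity settings delta.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

TASKS = ("vaccination", "screening")
N_CLASSES = 6

#: background exposure weight per task (ambient awareness, no paid media)
W_BG_DEFAULT = {"vaccination": 0.12, "screening": 0.10}

#: loss-framing multiplier grids (Table-specified per task)
FRAMING_GRID = {
    "vaccination": (0.95, 1.00, 1.05, 1.10),
    "screening": (1.05, 1.10, 1.15, 1.20),
}

#: lowest-baseline-uptake class per task (target of scenario K's boost)
LOWEST_BASELINE_CLASS = {"vaccination": 6, "screening": 1}

# class-independent (W_TV, W_DG, W_PR) rows; K and L are class-dependent
_FIXED_WEIGHTS = {
    "A": (0.000, 0.000, 0.000),
    "B": (0.100, 0.000, 0.000),
    "C": (0.000, 0.100, 0.000),
    "D": (0.000, 0.000, 0.100),
    "E": (0.050, 0.050, 0.000),
    "F": (0.050, 0.000, 0.050),
    "G": (0.000, 0.050, 0.050),
    "H": (0.033, 0.033, 0.033),
    "I": (0.025, 0.025, 0.000),
    "J": (0.200, 0.200, 0.000),
}

_NAMES = {
    "A": "Control (background only)", "B": "TV-only", "C": "Digital-only",
    "D": "Print-only", "E": "TV + digital", "F": "TV + print",
    "G": "Digital + print", "H": "All channels", "I": "Low-budget",
    "J": "High-budget", "K": "Equity-focused reweighting",
    "L": "Class-tailored channel portfolios", "M": "TV (loss framing)",
    "N": "Digital (loss framing)", "O": "TV + digital (loss framing)",
}

_FRAMING_BASE = {"M": "B", "N": "C", "O": "E"}  # M/N/O reuse these weights


def _check_task(task: str) -> None:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One campaign design.

    ``k_neg`` multiplies the TV and digital exposure terms (framing scenarios
    only); ``delta`` sets the intensity of scenario K's reweighting;
    ``regenerate_networks`` is False for the fixed-budget channel-mix block
    (A-H) and True for intervention/framing variants (I-O).
    """

    id: str
    name: str
    task: str
    w_bg: float
    k_neg: float = 1.0
    delta: float = 0.02
    regenerate_networks: bool = False

    @property
    def is_framing(self) -> bool:
        return self.id in _FRAMING_BASE

    def with_kneg(self, k_neg: float) -> "ScenarioSpec":
        if not self.is_framing:
            raise ValueError(f"scenario {self.id} has no framing multiplier")
        return replace(self, k_neg=float(k_neg))


def weights_for(spec: ScenarioSpec, class_k: int, task: str | None = None
                ) -> tuple[float, float, float]:
    """Base (W_TV, W_DG, W_PR) for one latent class, before framing.

    The framing multiplier k_neg is applied to exposure *terms* at simulation
    time (TV and digital only), not folded into these base weights.
    """
    task = spec.task if task is None else task
    _check_task(task)
    if not 1 <= class_k <= N_CLASSES:
        raise ValueError(f"class {class_k} out of 1..{N_CLASSES}")
    sid = spec.id
    if sid in _FIXED_WEIGHTS:
        return _FIXED_WEIGHTS[sid]
    if sid in _FRAMING_BASE:
        return _FIXED_WEIGHTS[_FRAMING_BASE[sid]]
    if sid == "K":
        delta = spec.delta
        if delta not in (0.02, 0.05):
            raise ValueError(f"scenario K delta must be 0.02 or 0.05, got {delta}")
        low = LOWEST_BASELINE_CLASS[task]
        if class_k == low:
            boost = 0.10 + delta
            # vaccination boosts digital for class 6; screening boosts TV for class 1
            return (0.0, boost, 0.0) if task == "vaccination" else (boost, 0.0, 0.0)
        w = 0.05 - delta / 10.0
        return (w, w, 0.0)
    if sid == "L":
        if class_k in (1, 5):      # TV-dominant media profiles
            return (0.10, 0.0, 0.0)
        if class_k == 6:           # digital-dominant profile
            return (0.0, 0.10, 0.0)
        return (0.05, 0.05, 0.0)   # mixed profiles (classes 2-4)
    raise ValueError(f"unknown scenario id {sid!r}")


def class_weight_matrix(spec: ScenarioSpec) -> np.ndarray:
    """(6, 3) matrix of base channel weights by class."""
    return np.array([weights_for(spec, k) for k in range(1, N_CLASSES + 1)])


def effective_agent_weights(spec: ScenarioSpec, posterior: np.ndarray,
                            modal_class: int | None = None,
                            personalization_mode: str = "posterior"
                            ) -> np.ndarray:
    """Resolve one agent's channel weights.

    ``posterior`` mode (default) mixes the class rows by the agent's posterior
    membership probabilities, propagating classification uncertainty;
    ``modal`` mode uses the hard modal class. The two coincide for
    class-independent scenarios and for one-hot posteriors.
    """
    W = class_weight_matrix(spec)
    if personalization_mode == "posterior":
        posterior = np.asarray(posterior, float)
        return posterior @ W
    if personalization_mode == "modal":
        if modal_class is None:
            modal_class = int(np.argmax(posterior)) + 1
        return W[modal_class - 1]
    raise ValueError(f"unknown personalization mode {personalization_mode!r}")


def catalog(task: str, delta: float = 0.02,
            framing_kneg: str = "midpoint") -> list[ScenarioSpec]:
    """All 15 scenarios for one task, ids A..O exactly once.

    Framing scenarios (M-O) carry a single representative k_neg for ranking
    analyses — the midpoint of the task's grid by default, or the value named
    by ``framing_kneg`` ("low"/"high"/a float). The full grid is available as
    :data:`FRAMING_GRID` and via :func:`framing_variants`.
    """
    _check_task(task)
    if framing_kneg == "midpoint":
        kneg = float(np.mean(FRAMING_GRID[task]))
    elif framing_kneg == "low":
        kneg = FRAMING_GRID[task][0]
    elif framing_kneg == "high":
        kneg = FRAMING_GRID[task][-1]
    else:
        kneg = float(framing_kneg)
    out = []
    for sid in "ABCDEFGHIJKLMNO":
        out.append(ScenarioSpec(
            id=sid, name=_NAMES[sid], task=task, w_bg=W_BG_DEFAULT[task],
            k_neg=kneg if sid in _FRAMING_BASE else 1.0, delta=delta,
            regenerate_networks=sid >= "I",
        ))
    return out


def get_scenario(task: str, sid: str, **kw) -> ScenarioSpec:
    specs = {s.id: s for s in catalog(task, **kw)}
    if sid not in specs:
        raise ValueError(f"unknown scenario id {sid!r}")
    return specs[sid]


def framing_variants(spec: ScenarioSpec) -> list[ScenarioSpec]:
    """The framing scenario at every k_neg on its task's grid."""
    return [spec.with_kneg(k) for k in FRAMING_GRID[spec.task]]


def validate_budget(spec: ScenarioSpec, tol: float = 1e-3) -> dict:
    """Check the budget invariants of one scenario.

    B-H: channel weights sum to ~0.10 (rounding slack per the design tables);
    K: unweighted class-average TV+digital budget exactly 0.10; A zero media;
    I and J are intentional budget variants and exempt from the 0.10 sum.
    Returns a report dict; raises ValueError on violation.
    """
    W = class_weight_matrix(spec)
    report = {"scenario": spec.id, "task": spec.task, "checks": [], "exempt": False}
    if np.any(W < 0):
        raise ValueError(f"scenario {spec.id}: negative weight")
    if spec.id == "A":
        if W.sum() != 0:
            raise ValueError("scenario A must have zero media weights")
        report["checks"].append("zero-media")
    elif spec.id in ("I", "J"):
        report["exempt"] = True  # intentional low/high budget variants
    elif spec.id == "K":
        avg = W[:, :2].sum() / N_CLASSES
        if abs(avg - 0.10) > 1e-9:
            raise ValueError(
                f"scenario K class-average TV+DG budget {avg:.6f} != 0.10")
        report["checks"].append("class-average-budget-0.10")
    else:
        for k in range(N_CLASSES):
            s = W[k].sum()
            if not 0.10 - tol <= s <= 0.10 + tol:
                raise ValueError(
                    f"scenario {spec.id} class {k + 1}: weight sum {s:.4f} "
                    "outside ~0.10")
        report["checks"].append("per-class-sum-~0.10")
    report["ok"] = True
    return report


def catalog_to_dict(task: str, **kw) -> list[dict]:
    """Serializable audit view of the scenario catalog."""
    out = []
    for s in catalog(task, **kw):
        out.append({
            "id": s.id, "name": s.name, "task": s.task, "w_bg": s.w_bg,
            "k_neg": s.k_neg, "delta": s.delta,
            "regenerate_networks": s.regenerate_networks,
            "class_weights": class_weight_matrix(s).tolist(),
        })
    return out
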