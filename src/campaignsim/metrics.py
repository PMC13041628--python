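"""Outcome summaries and distributional-equity metrics.

Primary outcomes are final adoption at month 12 and mean time to adoption
among adopters. Equity across the six latent classes is summarized by five
distributional metrics — minimum class-level adoption (A_min), the 90-10
percentile gap in percentage points, the relative disparity index
(RDI = max/min), Theil's T, and the Atkinson index at epsilon = 0.5 — and
screened against planning guardrails A_min >= 0.60, 90-10 gap <= 25 pp, and
RDI <= 1.5. Theil and Atkinson are reported descriptively only.

Percentiles use linear interpolation between order statistics throughout
(the numpy default), both for the 90-10 gap over the six class values and
for Monte Carlo percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GUARDRAILS = (0.60, 0.25, 1.5)  # (A_min floor, 90-10 gap cap, RDI cap)


def final_adoption(result) -> float:
    """Proportion of agents in the adopted state at the horizon."""
    if result.n == 0:
        raise ValueError("empty simulation result")
    return float(np.mean(result.state == 2))


def awareness_rate(result) -> float:
    """Proportion of agents ever aware (adoption implies awareness)."""
    return float(np.mean(result.state >= 1))


def mean_time_to_adoption(result) -> float | None:
    """Mean adoption month among adopters; None when nobody adopted."""
    times = result.t_adopt[result.t_adopt > 0]
    return float(times.mean()) if times.size else None


def class_adoption(result, modal_classes, n_classes: int = 6) -> np.ndarray:
    """Per-class adoption proportions in fixed class order 1..n_classes."""
    modal_classes = np.asarray(modal_classes)
    out = np.empty(n_classes)
    for k in range(1, n_classes + 1):
        mask = modal_classes == k
        if not mask.any():
            raise ValueError(f"class {k} is empty")
        out[k - 1] = np.mean(result.state[mask] == 2)
    return out


def gap_90_10(class_values) -> float:
    """(P90 - P10) x 100 over class-level values, in percentage points,
    with linear interpolation between order statistics."""
    v = np.asarray(class_values, float)
    if v.size < 2:
        raise ValueError("need at least 2 classes")
    p90, p10 = np.percentile(v, [90, 10])
    return float((p90 - p10) * 100.0)


def rdi(class_values) -> float:
    """Relative disparity index: max / min of class-level adoption."""
    v = np.asarray(class_values, float)
    if v.min() <= 0:
        return float("inf")
    return float(v.max() / v.min())


def _weights(values, weights):
    v = np.asarray(values, float)
    if np.any(v <= 0):
        raise ValueError("inequality indices require strictly positive values")
    w = np.ones_like(v) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return v, w / w.sum()


def theil_T(values, weights=None) -> float:
    """Theil's T: sum_k w_k (x_k/mu) ln(x_k/mu), mu = sum w_k x_k.

    ``weights`` are class sizes (population shares); equal weights when None.
    Zero iff all values equal; scale-invariant.
    """
    v, w = _weights(values, weights)
    mu = float(w @ v)
    r = v / mu
    return float(w @ (r * np.log(r)))


def atkinson(values, weights=None, epsilon: float = 0.5) -> float:
    """Atkinson index 1 - [sum_k w_k (x_k/mu)^(1-eps)]^(1/(1-eps)), 0<eps<1."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    v, w = _weights(values, weights)
    mu = float(w @ v)
    return float(1.0 - (w @ (v / mu) ** (1 - epsilon)) ** (1.0 / (1 - epsilon)))


@dataclass
class EquityReport:
    """Class-level adoption with the five distributional metrics and the
    guardrail verdicts."""

    class_adoption: np.ndarray
    a_min: float
    gap_90_10: float      # percentage points
    rdi: float
    theil_T: float
    atkinson: float
    pass_a_min: bool
    pass_gap: bool
    pass_rdi: bool
    pass_all: bool


def guardrail_screen(class_values, class_sizes=None,
                     thresholds=GUARDRAILS) -> EquityReport:
    """Compute the equity metrics for one class-adoption vector and screen
    them against the guardrails (Theil/Atkinson are descriptive only).

    The 90-10 gap and RDI use the unweighted class-level values (percentiles
    of class-level adoption); Theil and Atkinson weight by class size when
    sizes are given.
    """
    v = np.asarray(class_values, float)
    floor, gap_cap, rdi_cap = thresholds
    a_min = float(v.min())
    gap = gap_90_10(v)
    ratio = rdi(v)
    ok_min = a_min >= floor
    ok_gap = gap / 100.0 <= gap_cap
    ok_rdi = ratio <= rdi_cap
    return EquityReport(
        class_adoption=v, a_min=a_min, gap_90_10=gap, rdi=ratio,
        theil_T=theil_T(v, class_sizes), atkinson=atkinson(v, class_sizes),
        pass_a_min=ok_min, pass_gap=ok_gap, pass_rdi=ok_rdi,
        pass_all=ok_min and ok_gap and ok_rdi)


def synergy_index(mix_adoption: float, single_adoptions) -> float:
    """(mixed-strategy adoption - best single-channel adoption) x 100, in
    percentage points; negative values indicate dilution."""
    singles = np.asarray(single_adoptions, float)
    if singles.size == 0:
        raise ValueError("need at least one single-channel value")
    return float((mix_adoption - singles.max()) * 100.0)
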