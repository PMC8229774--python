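"""Deterministic model of Y-lineage expansion under heritable male dominance.

A fraction d of males ("dominant", e.g. headmen with the prerogative of
polygyny) enjoy a mating-success multiplier b >= 1 and pass their status to
sons with fidelity tau. The model tracks the population frequency p of a
patriline (Y lineage) and the fraction q of dominant males who carry it.
With full fidelity and a lineage-founded dominant class (tau=1, q0=1) the
recursion has the closed form p_t = 1 - (1 - p0) / W**t with
W = b*d + 1 - d, so the lineage grows geometrically toward fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "DominanceModel",
    "Trajectory",
    "step",
    "trajectory",
    "closed_form_frequency",
    "required_advantage",
    "advantage_grid",
]


@dataclass(frozen=True)
class DominanceModel:
    """Parameters of the dominance recursion.

    d: dominant fraction of males, in (0, 1).
    b: mating-success multiplier of dominant males, >= 1.
    tau: father-to-son status-transmission fidelity, in [0, 1].
    p0: initial lineage frequency, in (0, 1].
    q0: initial fraction of dominant males carrying the lineage, in [0, 1].
    """

    d: float = 0.05
    b: float = 3.0
    tau: float = 1.0
    p0: float | None = None
    q0: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.d < 1):
            raise ValueError("d must be in (0, 1)")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if not (0 <= self.tau <= 1):
            raise ValueError("tau must be in [0, 1]")
        if not (0 <= self.q0 <= 1):
            raise ValueError("q0 must be in [0, 1]")
        if self.p0 is None:
            # lineage founded by the dominant class itself
            object.__setattr__(self, "p0", self.d * self.q0)
        if not (0 < self.p0 <= 1):
            raise ValueError("p0 must be in (0, 1]")


@dataclass
class Trajectory:
    p: np.ndarray  # lineage frequency per generation, length T+1
    q: np.ndarray  # dominant-carrier fraction per generation
    clamped: bool = False

    @property
    def horizon(self) -> int:
        return self.p.size - 1


def step(
    state: tuple[float, float], model: DominanceModel
) -> tuple[float, float, bool]:
    """One generation of the recursion: (p, q) -> (p', q', clamped).

    Sons pick fathers proportionally to mating success, so sons of dominant
    fathers form a fraction b*d/W of the next generation with
    W = b*d + 1 - d. The new dominant class (size d) reserves a fraction
    tau of its slots for sons of dominant fathers, lineage sons first; the
    rest is filled at random from the remaining sons.
    """
    p, q = state
    d, b, tau = model.d, model.b, model.tau
    w = b * d + 1 - d
    dq = min(d * q, p)  # lineage mass inside the dominant class
    p_next = (b * d * q + (p - dq)) / w
    sons_dom = b * d / w  # sons of dominant fathers
    sons_dom_lin = b * dq / w  # ... who carry the lineage
    a = min(tau * d, sons_dom)  # slots filled from dominant-father sons
    lin_in_a = min(a, sons_dom_lin)
    rest_slots = d - a
    rest_lin = (p_next - lin_in_a) / (1 - a) if a < 1 else 0.0
    q_next = (lin_in_a + rest_slots * rest_lin) / d
    clamped = not (0 <= p_next <= 1 and 0 <= q_next <= 1)
    return min(max(p_next, 0.0), 1.0), min(max(q_next, 0.0), 1.0), clamped


def trajectory(model: DominanceModel, T: int) -> Trajectory:
    """Iterate the recursion for T generations from (p0, q0)."""
    if T < 0:
        raise ValueError("T must be >= 0")
    p = np.empty(T + 1)
    q = np.empty(T + 1)
    p[0], q[0] = model.p0, model.q0
    any_clamp = False
    for t in range(T):
        p[t + 1], q[t + 1], clamped = step((p[t], q[t]), model)
        any_clamp = any_clamp or clamped
    return Trajectory(p=p, q=q, clamped=any_clamp)


def closed_form_frequency(model: DominanceModel, t) -> np.ndarray:
    """Closed-form p_t for the tau=1, q0=1 special case."""
    if not (model.tau == 1.0 and model.q0 == 1.0):
        raise ValueError("closed form requires tau=1 and q0=1")
    w = model.b * model.d + 1 - model.d
    t = np.asarray(t, dtype=float)
    return 1.0 - (1.0 - model.p0) / w**t


def required_advantage(
    target_p: float,
    T: int,
    model_sans_b: DominanceModel,
    b_max: float = 1000.0,
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Smallest mating-success multiplier b reaching target_p in T generations.

    Bisection on b in [1, b_max]; returns (b*, attainable). When even b_max
    cannot reach the target, (b_max, False) is returned.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if target_p <= model_sans_b.p0:
        return 1.0, True

    def final_p(b: float) -> float:
        return trajectory(replace(model_sans_b, b=b), T).p[-1]

    if final_p(b_max) < target_p:
        return b_max, False
    lo, hi = 1.0, b_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if final_p(mid) >= target_p:
            hi = mid
        else:
            lo = mid
    return hi, True


def advantage_grid(
    model_template: DominanceModel,
    d_values,
    tau_values,
    T_values,
    target_p: float,
) -> pd.DataFrame:
    """required_advantage over a (d, tau, T) grid for sensitivity analysis."""
    rows = []
    for d, tau, T in product(d_values, tau_values, T_values):
        m = replace(model_template, d=d, tau=tau, b=1.0)
        b_star, attainable = required_advantage(target_p, T, m)
        rows.append(
            {
                "d": d,
                "tau": tau,
                "T": T,
                "target_p": target_p,
                "b_star": b_star,
                "attainable": attainable,
            }
        )
    return pd.DataFrame(rows)
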