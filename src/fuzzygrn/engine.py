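"""Semi-quantitative execution of the regulatory Petri net.

Entity activity is carried on a continuous [0, 1] scale around a neutral
baseline (default 0.5).  A fuzzy partition with seven triangular terms —
down_strong … neutral … up_strong, centers spaced 0.15 apart around the
baseline — translates a level into degrees of membership in the discrete
regulator states used by the curated transitions.  A transition fires to
the degree that all of its inputs are satisfied (fuzzy AND = minimum): a
signal required present contributes its level, required absent contributes
1 − level, and a TF input contributes the membership of its required
(direction, magnitude) term.  Firing transitions push their targets away
from baseline by a signed step per magnitude (weak ±0.15, medium ±0.30,
strong ±0.45), summed over transitions and clipped to [0, 1].

This realizes the differential regulation setting of the curated model: the
presence or absence of a signal enables specific TFs, which in turn move
their targets up or down relative to the opposite signal state.  The
update is synchronous and deterministic; iteration stops at a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .model import Network, Transition, UnknownEntityError

__all__ = [
    "TERMS",
    "EngineParams",
    "SystemState",
    "FuzzyMembership",
    "SimulationResult",
    "fuzzify",
    "transition_firing_degree",
    "step",
    "simulate",
    "differential_response",
]

TERMS = (
    "down_strong",
    "down_medium",
    "down_weak",
    "neutral",
    "up_weak",
    "up_medium",
    "up_strong",
)

# signed center offsets from baseline, index-aligned with TERMS
_OFFSETS = (-0.45, -0.30, -0.15, 0.0, 0.15, 0.30, 0.45)

_STEPS = {"weak": 0.15, "medium": 0.30, "strong": 0.45}


@dataclass(frozen=True)
class EngineParams:
    """Tunable constants of the execution semantics."""

    baseline: float = 0.5
    step_weak: float = 0.15
    step_medium: float = 0.30
    step_strong: float = 0.45
    tol: float = 1e-6
    max_iter: int = 100

    def step_for(self, magnitude: str) -> float:
        return {"weak": self.step_weak, "medium": self.step_medium, "strong": self.step_strong}[
            magnitude
        ]


@dataclass
class SystemState:
    """Semi-quantitative levels of all entities; unspecified ⇒ baseline."""

    levels: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.5

    def __post_init__(self):
        for eid, v in self.levels.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"level of {eid!r} out of [0,1]: {v}")
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError(f"baseline out of [0,1]: {self.baseline}")

    def level(self, entity_id: str) -> float:
        return self.levels.get(entity_id, self.baseline)

    def copy(self) -> "SystemState":
        return SystemState(dict(self.levels), self.baseline)


@dataclass(frozen=True)
class FuzzyMembership:
    """Degrees over the seven discrete regulation terms; they sum to 1."""

    terms: dict[str, float]

    def degree(self, term: str) -> float:
        return self.terms.get(term, 0.0)

    def direction_degree(self, direction: str) -> float:
        """Total membership in the three terms of one direction."""
        return sum(v for k, v in self.terms.items() if k.startswith(direction + "_"))


@dataclass
class SimulationResult:
    final: SystemState
    trajectory: list[SystemState]
    converged: bool
    iterations: int


def fuzzify(level: float, baseline: float = 0.5) -> FuzzyMembership:
    """Membership of a level in the seven-term triangular partition.

    Term centers sit at baseline + {−0.45 … +0.45}; each triangle spans its
    two neighbours, so the degrees form a partition of unity between the
    extreme centers.  Levels beyond the extreme centers belong fully to the
    extreme term (shoulder), so level 1.0 at baseline 0.5 is pure up_strong.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level out of [0,1]: {level}")
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline out of [0,1]: {baseline}")
    centers = [baseline + o for o in _OFFSETS]
    deg = {t: 0.0 for t in TERMS}
    if level <= centers[0]:
        deg[TERMS[0]] = 1.0
    elif level >= centers[-1]:
        deg[TERMS[-1]] = 1.0
    else:
        for i in range(len(centers) - 1):
            lo, hi = centers[i], centers[i + 1]
            if lo <= level <= hi:
                frac = (level - lo) / (hi - lo)
                deg[TERMS[i]] = 1.0 - frac
                deg[TERMS[i + 1]] = frac
                break
    return FuzzyMembership(deg)


def _input_degree(inp, state: SystemState) -> float:
    lvl = state.level(inp.entity_id)
    st = inp.state
    if st.direction == "present":
        return lvl
    if st.direction == "absent":
        return 1.0 - lvl
    membership = fuzzify(lvl, state.baseline)
    if st.special == "knockout":
        return membership.degree("down_strong")
    if st.special == "overexpression":
        return membership.degree("up_strong")
    if st.magnitude == "na":
        # sign known but strength unstated: any term of that direction
        return min(1.0, membership.direction_degree(st.direction))
    return membership.degree(f"{st.direction}_{st.magnitude}")


def transition_firing_degree(transition: Transition, state: SystemState) -> float:
    """Fuzzy AND (minimum) of the satisfaction degrees of all inputs."""
    if not transition.inputs:
        return 0.0
    return min(_input_degree(inp, state) for inp in transition.inputs)


def step(
    network: Network,
    state: SystemState,
    params: EngineParams | None = None,
    clamped: frozenset[str] | set[str] = frozenset(),
) -> SystemState:
    """One synchronous update of all regulated entities.

    Each entity targeted by at least one transition is re-set to
    baseline + Σ firing_degree × signed step(magnitude), clipped to [0, 1];
    untargeted entities and clamped entities (contexts and perturbations)
    keep their level.
    """
    params = params or EngineParams(baseline=state.baseline)
    contrib: dict[str, float] = {}
    for tr in network.transitions.values():
        degree = transition_firing_degree(tr, state)
        for out in tr.outputs:
            sign = 1.0 if out.direction == "up" else -1.0
            contrib[out.entity_id] = contrib.get(out.entity_id, 0.0) + (
                degree * sign * params.step_for(out.magnitude)
            )
    new = state.copy()
    for eid, delta in contrib.items():
        if eid in clamped:
            continue
        new.levels[eid] = min(1.0, max(0.0, params.baseline + delta))
    return new


def simulate(
    network: Network,
    context: dict[str, str] | None = None,
    perturbations: dict[str, str] | None = None,
    params: EngineParams | None = None,
    max_iter: int | None = None,
    tol: float | None = None,
) -> SimulationResult:
    """Iterate the synchronous update to a fixed point under a context.

    ``context`` clamps signals to present (1) or absent (0);
    ``perturbations`` clamps TFs to knockout (0) or overexpression (1).
    Clamped entities are never updated.  Stops when the largest level change
    falls below ``tol`` or after ``max_iter`` sweeps.
    """
    context = context or {}
    perturbations = perturbations or {}
    params = params or EngineParams()
    if max_iter is not None:
        params = replace(params, max_iter=max_iter)
    if tol is not None:
        params = replace(params, tol=tol)

    levels: dict[str, float] = {}
    for sig, val in context.items():
        if sig not in network.entities:
            raise UnknownEntityError(sig)
        if val not in ("present", "absent"):
            raise ValueError(f"context value for {sig!r} must be present or absent, got {val!r}")
        levels[sig] = 1.0 if val == "present" else 0.0
    for tf, val in perturbations.items():
        if tf not in network.entities:
            raise UnknownEntityError(tf)
        if val not in ("knockout", "overexpression"):
            raise ValueError(
                f"perturbation for {tf!r} must be knockout or overexpression, got {val!r}"
            )
        levels[tf] = 0.0 if val == "knockout" else 1.0
    clamped = frozenset(levels)

    state = SystemState(levels, params.baseline)
    trajectory = [state.copy()]
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        new = step(network, state, params, clamped)
        delta = max(
            (abs(new.level(e) - state.level(e)) for e in set(new.levels) | set(state.levels)),
            default=0.0,
        )
        trajectory.append(new.copy())
        state = new
        if delta < params.tol:
            converged = True
            break
    return SimulationResult(final=state, trajectory=trajectory, converged=converged,
                            iterations=iterations)


def differential_response(
    network: Network,
    context_a: dict[str, str],
    context_b: dict[str, str],
    perturbations: dict[str, str] | None = None,
    params: EngineParams | None = None,
) -> dict[str, tuple[str, str]]:
    """Discretized per-target change when switching context A → context B.

    Simulates both contexts and maps each regulated entity's fixed-point
    level difference back onto the discrete scale: |Δ| < 0.15 weak,
    [0.15, 0.30) medium, ≥ 0.30 strong; differences below the convergence
    tolerance do not register.
    """
    params = params or EngineParams()
    res_a = simulate(network, context_a, perturbations, params)
    res_b = simulate(network, context_b, perturbations, params)
    targets = {out.entity_id for tr in network.transitions.values() for out in tr.outputs}
    out: dict[str, tuple[str, str]] = {}
    for tg in sorted(targets):
        delta = res_b.final.level(tg) - res_a.final.level(tg)
        if abs(delta) < params.tol:
            continue
        direction = "up" if delta > 0 else "down"
        mag = abs(delta)
        if mag < params.step_weak:
            magnitude = "weak"
        elif mag < params.step_medium:
            magnitude = "medium"
        else:
            magnitude = "strong"
        out[tg] = (direction, magnitude)
    return out
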