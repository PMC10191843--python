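"""Kok-cycle S-state population bookkeeping.

Photosystem II advances through the storage states S0->S1->S2->S3->(S4)->S0
one step per saturating light flash, but with an intrinsic probability per
flash (the "miss factor") of failing to advance, and a small probability of
advancing twice ("double hit").  Over a flash train this mixes the S-state
populations, so every time-resolved dataset probes a mixture of reaction
centers: those advancing through the probed transition, those lagging one
step behind, and (at long pump-probe delays) those that have already
completed the transition.  This module propagates populations through a
flash protocol and splits a time point into those refinement components,
applying the convention that component populations below a noise floor
cannot be modelled and are redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "S_STATES",
    "SStatePopulation",
    "FlashProtocol",
    "ComponentSplit",
    "transition_matrix",
    "propagate_flashes",
    "enumerate_outcomes",
    "assign_components",
    "apply_noise_floor",
    "exponential_completion",
]

S_STATES = ("S0", "S1", "S2", "S3")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SStatePopulation:
    """Fractions of PS II centers in each storage state S0..S3."""

    fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.shape != (4,):
            raise ValueError("fractions must have exactly four entries (S0..S3)")
        if np.any(arr < -_SUM_TOL) or np.any(arr > 1 + _SUM_TOL):
            raise ValueError(f"fractions must lie in [0, 1], got {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got sum {arr.sum()!r}")
        object.__setattr__(self, "fractions", tuple(float(x) for x in arr))

    @classmethod
    def pure(cls, state: str) -> "SStatePopulation":
        if state not in S_STATES:
            raise ValueError(f"unknown S-state {state!r}")
        vec = [0.0] * 4
        vec[S_STATES.index(state)] = 1.0
        return cls(tuple(vec))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SStatePopulation":
        return cls(tuple(float(d.get(s, 0.0)) for s in S_STATES))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def __getitem__(self, state: str) -> float:
        return self.fractions[S_STATES.index(state)]


@dataclass(frozen=True)
class FlashProtocol:
    """A train of saturating visible flashes with per-flash inefficiencies.

    Parameters
    ----------
    n_flashes : number of flashes applied to the dark-adapted sample.
    miss : probability per flash that a center fails to advance.
    double_hit : probability per flash of advancing two states.
    probe_delay_us : delay between the final flash and the X-ray probe,
        in microseconds.  Not used by the propagation itself (flash spacing
        is long enough that back-reactions are neglected) but carried so a
        protocol fully labels a dataset.
    """

    n_flashes: int
    miss: float = 0.0
    double_hit: float = 0.0
    probe_delay_us: float = 0.0

    def __post_init__(self) -> None:
        if self.n_flashes < 0:
            raise ValueError(f"n_flashes must be >= 0, got {self.n_flashes}")
        for name in ("miss", "double_hit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.miss + self.double_hit > 1.0 + _SUM_TOL:
            raise ValueError(
                f"miss + double_hit must be <= 1, got {self.miss + self.double_hit}"
            )
        if self.probe_delay_us < 0:
            raise ValueError("probe_delay_us must be >= 0")


@dataclass(frozen=True)
class ComponentSplit:
    """Refinement components of one time point.

    ``primary`` are the centers advancing through the probed transition (the
    refinable intermediate), ``secondary`` the centers lagging one transition
    behind, and ``tertiary`` (possibly absent) the centers that have already
    completed the transition.  Labels name the structural state used to model
    each component.
    """

    primary: tuple[str, float]
    secondary: tuple[str, float]
    tertiary: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for name, frac in self.items():
            if not -_SUM_TOL <= frac <= 1 + _SUM_TOL:
                raise ValueError(f"component {name!r} fraction {frac} outside [0, 1]")
        if abs(self.total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {self.total}")

    def items(self) -> list[tuple[str, float]]:
        out = [self.primary, self.secondary]
        if self.tertiary is not None:
            out.append(self.tertiary)
        return out

    @property
    def total(self) -> float:
        return sum(f for _, f in self.items())

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.items()])

    def to_frame(self, time_point_us: float | None = None) -> pd.DataFrame:
        rows = [
            {"component_label": lab, "fraction": frac, "role": role}
            for role, (lab, frac) in zip(
                ("primary", "secondary", "tertiary"), self.items()
            )
        ]
        df = pd.DataFrame(rows)
        if time_point_us is not None:
            df.insert(0, "time_point_us", time_point_us)
        return df


def transition_matrix(protocol: FlashProtocol) -> np.ndarray:
    """Column-stochastic 4x4 single-flash transition matrix over S0..S3.

    Column j holds the probabilities of a center in state Sj ending up in
    each state after one flash: advance one step with probability
    ``1 - miss - double_hit`` (S3 wraps to S0), stay with probability
    ``miss``, advance two steps with probability ``double_hit``.
    """
    p_hit = 1.0 - protocol.miss - protocol.double_hit
    M = np.zeros((4, 4))
    for j in range(4):
        M[j, j] += protocol.miss
        M[(j + 1) % 4, j] += p_hit
        M[(j + 2) % 4, j] += protocol.double_hit
    return M


def propagate_flashes(
    initial: SStatePopulation, protocol: FlashProtocol
) -> SStatePopulation:
    """Population after applying the protocol's full flash train."""
    M = transition_matrix(protocol)
    vec = np.linalg.matrix_power(M, protocol.n_flashes) @ initial.as_array()
    vec = np.clip(vec, 0.0, 1.0)
    return SStatePopulation(tuple(vec / vec.sum()))


def enumerate_outcomes(
    initial: SStatePopulation, protocol: FlashProtocol
) -> SStatePopulation:
    """Brute-force propagation enumerating every hit/miss/double-hit sequence.

    Exponential in ``n_flashes``; intended as an independent oracle for
    :func:`propagate_flashes` at small flash counts.
    """
    probs = {0: protocol.miss, 1: 1.0 - protocol.miss - protocol.double_hit,
             2: protocol.double_hit}
    vec = np.zeros(4)
    for start in range(4):
        p0 = initial.as_array()[start]
        if p0 == 0.0:
            continue
        paths = [(start, p0)]
        for _ in range(protocol.n_flashes):
            paths = [
                ((s + step) % 4, p * probs[step])
                for s, p in paths
                for step in (0, 1, 2)
                if probs[step] > 0.0
            ]
        for s, p in paths:
            vec[s] += p
    return SStatePopulation(tuple(vec / vec.sum()))


def _probed_transition(flash_index: int) -> tuple[str, str]:
    """Transition probed by flash number ``flash_index`` from dark-adapted S1."""
    if flash_index < 1:
        raise ValueError(
            f"flash_index must be >= 1 (no transition defined for {flash_index})"
        )
    i = (1 + flash_index - 1) % 4
    return S_STATES[i], S_STATES[(i + 1) % 4]


def assign_components(
    populations_after_flash: SStatePopulation,
    completed_fraction: float,
    flash_index: int,
) -> ComponentSplit:
    """Split a time point into primary/secondary/tertiary refinement components.

    The advancing fraction is the population found in the probed transition's
    product state after the final flash (for the third flash: the centers
    promoted from S3 toward S0).  Of those, ``completed_fraction`` have
    already reached the product state's stable structure (tertiary); the rest
    are mid-transition (primary).  Everything else is lagging (secondary),
    modelled from the reactant-state structure.
    """
    if not 0.0 <= completed_fraction <= 1.0:
        raise ValueError(f"completed_fraction must lie in [0, 1], got {completed_fraction}")
    donor, product = _probed_transition(flash_index)
    advancing = populations_after_flash[product]
    lagging = 1.0 - advancing
    primary = advancing * (1.0 - completed_fraction)
    tertiary = advancing * completed_fraction
    return ComponentSplit(
        primary=(f"{donor}->{product}", primary),
        secondary=(donor, lagging),
        tertiary=(product, tertiary),
    )


def apply_noise_floor(split: ComponentSplit, threshold: float = 0.10) -> ComponentSplit:
    """Zero out components below the modelling noise floor and renormalize.

    Populations below ~10% are within the noise of the structural refinement
    and cannot be modelled as separate components; their mass is
    redistributed proportionally among the surviving components.
    """
    fracs = split.fractions
    keep = fracs >= threshold
    if not keep.any():
        raise ValueError("all component fractions below the noise floor; degenerate split")
    floored = np.where(keep, fracs, 0.0)
    floored = floored / floored.sum()
    items = split.items()
    new = [(lab, float(f)) for (lab, _), f in zip(items, floored)]
    tertiary = new[2] if len(new) == 3 else None
    # a floored (zero) tertiary collapses to a two-component model
    if tertiary is not None and tertiary[1] == 0.0:
        tertiary = None
    return ComponentSplit(primary=new[0], secondary=new[1], tertiary=tertiary)


def exponential_completion(tau_us: float) -> Callable[[float], float]:
    """Monotone completed-fraction model: 1 - exp(-t/tau)."""
    if tau_us <= 0:
        raise ValueError("tau_us must be > 0")

    def completed(t_us: float) -> float:
        return float(1.0 - np.exp(-max(t_us, 0.0) / tau_us))

    return completed
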