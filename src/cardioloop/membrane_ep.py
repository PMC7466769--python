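"""Human mid-myocardial ventricular myocyte electrophysiology.

This module wraps a ten Tusscher-type ionic model of the human M cell: nine
channels, four pumps, two exchangers, 17 state variables.  It supplies the
intracellular Ca2+ transient that drives the contractile model.  Six
parameters that are plausible pharmacological targets are exposed as
multiplicative factors on their published base values: the SR leak rate
(Ca_Vleak), the maximal SERCA uptake rate (Ca_Vmaxup), and the conductances
g_CaL, g_to, g_Kr and g_Ks.

The integrator is a hybrid scheme: exponential (Rush-Larsen) updates for the
12 gating variables — which therefore stay in [0, 1] without clamping — and
forward Euler for the membrane voltage and ionic concentrations, with
automatic sub-stepping during the action-potential upstroke.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _core

__all__ = [
    "EpParams", "EpState", "NumericalFailure",
    "ep_derivatives", "ep_step", "prepace_to_steady_state",
]

ADJUSTABLE_PARAMS = tuple(_core.EP_ADJUSTABLE)


class NumericalFailure(RuntimeError):
    """A state variable became non-finite or left its admissible range."""


@dataclass(frozen=True)
class EpParams:
    """Multipliers on the adjustable ionic-model parameters.

    All other constants are held at their published values.
    """

    Ca_Vleak: float = 1.0
    Ca_Vmaxup: float = 1.0
    g_CaL: float = 1.0
    g_to: float = 1.0
    g_Kr: float = 1.0
    g_Ks: float = 1.0

    def __post_init__(self):
        for name in ADJUSTABLE_PARAMS:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"multiplier {name} must be strictly positive")

    def vector(self) -> np.ndarray:
        """Effective 37-entry constant vector for the kernels."""
        p = _core.EP_BASE_VALUES.copy()
        for name, idx in _core.EP_ADJUSTABLE.items():
            p[idx] *= getattr(self, name)
        return p

    def multipliers(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ADJUSTABLE_PARAMS}


@dataclass
class EpState:
    """The 17 electrophysiological state variables."""

    values: np.ndarray = field(
        default_factory=lambda: _core.EP_INITIAL_STATE.copy())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (17,):
            raise ValueError("EP state vector must have exactly 17 entries")

    # named accessors
    @property
    def membrane_voltage(self) -> float:
        return float(self.values[0])

    @property
    def intracellular_Ca(self) -> float:
        return float(self.values[13])

    @property
    def SR_Ca(self) -> float:
        return float(self.values[14])

    @property
    def intracellular_Na(self) -> float:
        return float(self.values[15])

    @property
    def intracellular_K(self) -> float:
        return float(self.values[16])

    @property
    def gates(self) -> np.ndarray:
        return self.values[1:13]

    def validate(self) -> None:
        for k, name in enumerate(_core.EP_STATE_NAMES):
            if not np.isfinite(self.values[k]):
                raise NumericalFailure(f"EP state variable {name!r} is non-finite")
        g = self.gates
        # fCa's published steady-state expression tops out at 1.53/1.46
        # (slightly above 1 at diastolic Ca); every other gate stays in [0,1]
        upper = np.ones(12)
        upper[5] = 1.53 / 1.46
        if np.any(g < -1e-12) or np.any(g > upper + 1e-12):
            bad = _core.EP_STATE_NAMES[1 + int(np.argmax((g < 0) | (g > upper)))]
            raise NumericalFailure(f"gating variable {bad!r} left its range")
        if np.any(self.values[13:] <= 0.0):
            bad = _core.EP_STATE_NAMES[13 + int(np.argmax(self.values[13:] <= 0))]
            raise NumericalFailure(f"concentration {bad!r} is not positive")

    def copy(self) -> "EpState":
        return EpState(self.values.copy())

    # JSON round-trip for restart files
    def to_json(self) -> str:
        return json.dumps(dict(zip(_core.EP_STATE_NAMES, self.values.tolist())))

    @classmethod
    def from_json(cls, text: str) -> "EpState":
        d = json.loads(text)
        return cls(np.array([d[n] for n in _core.EP_STATE_NAMES], dtype=float))


def ep_derivatives(state: EpState, params: EpParams,
                   stimulus_current: float = 0.0) -> np.ndarray:
    """Time derivative (per ms) of the EP state.

    ``stimulus_current`` is in pA/pF; the printed pacing value of -52 pA/pF
    is depolarizing under this model's sign convention.
    """
    state.validate()
    return _core.ep_rhs(state.values, params.vector(), stimulus_current)


def ep_step(state: EpState, params: EpParams, dt: float,
            stimulus_current: float = 0.0) -> EpState:
    """Advance the EP state by ``dt`` ms."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    y = _core.ep_advance(state.values.copy(), params.vector(),
                         stimulus_current, dt)
    out = EpState(y)
    out.validate()
    return out


def prepace_to_steady_state(params: EpParams, n_beats: int = 1000,
                            rate: float = 1.0,
                            stim_amplitude: float = -52.0,
                            stim_duration: float = 3.0) -> EpState:
    """Pace the uncoupled myocyte to its limit cycle.

    Runs ``n_beats`` at ``rate`` Hz with ``stim_duration`` ms pulses of
    ``stim_amplitude`` pA/pF from the published resting state and returns the
    end-diastolic state used to initialize coupled simulations.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    period = 1000.0 / rate
    y, diff = _core.ep_prepace(_core.EP_INITIAL_STATE.copy(), params.vector(),
                               n_beats, period, stim_duration, stim_amplitude)
    if diff < 0.0:
        raise NumericalFailure(
            f"EP pre-pacing diverged at beat {int(-diff - 1)}")
    out = EpState(y)
    out.validate()
    return out


# cache of pre-paced states, keyed by (multipliers, n_beats, rate)
_PREPACE_CACHE: dict[tuple, np.ndarray] = {}


def prepaced_state_cached(params: EpParams, n_beats: int = 1000,
                          rate: float = 1.0) -> EpState:
    """Memoized :func:`prepace_to_steady_state` (the model is deterministic,
    so the cache is exact)."""
    key = (tuple(sorted(params.multipliers().items())), n_beats, rate)
    if key not in _PREPACE_CACHE:
        _PREPACE_CACHE[key] = prepace_to_steady_state(
            params, n_beats=n_beats, rate=rate).values
    return EpState(_PREPACE_CACHE[key].copy())
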