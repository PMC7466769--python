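"""Hemispherical ventricle and lumped-parameter systemic circulation.

The ventricle is an idealized thin-walled hemisphere.  Its internal radius
follows from the chamber volume, ``r = (3 V / 2 pi)^(1/3)``, the wall
thickness from wall-volume conservation, ``W_thickness = W_volume /
(2 pi r^2)``, and the chamber pressure from Laplace's law,
``P = 2 S ln(1 + W_thickness/r)`` (the thick-shell Laplace form, reducing to ``2 S W_thickness / r`` for thin walls) where ``S`` is the wall stress delivered by the
contractile model.  A contractile element embedded circumferentially in the
mid-transmural wall ties the half-sarcomere length to the chamber volume.

The systemic circulation is a series loop of five zero-dimensional
compartments (aorta, arteries, arterioles, capillaries, veins), each with a
compliance so that ``P_x = V_x / C_x``, connected by resistances with
Ohm's-law flows.  One-way valves gate flow out of (aortic) and into
(venous return) the ventricle.

Units: volumes liters, pressures mmHg, resistances mmHg s L^-1, lengths m
internally for geometry, half-sarcomere lengths nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core

__all__ = [
    "COMPARTMENTS", "VASCULAR_COMPARTMENTS", "CONNECTIONS",
    "VentricleGeometry", "CirculationParams", "CirculationState",
    "radius_from_volume", "volume_from_radius", "wall_thickness",
    "ventricular_pressure", "hs_length_from_volume",
    "compartment_pressures", "flows", "update_volumes",
]

COMPARTMENTS = ("ventricle", "aorta", "arteries", "arterioles",
                "capillaries", "veins")
VASCULAR_COMPARTMENTS = COMPARTMENTS[1:]
CONNECTIONS = ("aortic_valve", "arteries", "arterioles", "capillaries",
               "veins", "venous_return")


class DegenerateGeometryError(ValueError):
    pass


def radius_from_volume(V: float) -> float:
    """Internal radius (m) of a hemispherical chamber of volume ``V`` (L)."""
    if V <= 0.0:
        raise DegenerateGeometryError("ventricular volume must be positive")
    return float(_core.radius_from_volume_core(V))


def volume_from_radius(r: float) -> float:
    """Inverse of :func:`radius_from_volume` (returns liters)."""
    return float(2.0 * np.pi / 3.0 * r ** 3 * 1.0e3)


def wall_thickness(r: float, W_volume: float) -> float:
    """Wall thickness (m) conserving wall volume ``W_volume`` (L)."""
    return float(_core.wall_thickness_core(r, W_volume))


def ventricular_pressure(S: float, W_thickness: float, r: float) -> float:
    """Laplace-law chamber pressure (mmHg) from wall stress ``S`` (N/m^2)."""
    if r <= 0.0:
        raise DegenerateGeometryError("radius must be positive")
    return float(_core.ventricular_pressure_core(S, W_thickness, r))


@dataclass(frozen=True)
class VentricleGeometry:
    """Hemispherical ventricle at a given chamber volume."""

    V_ventricle: float        # L
    V_slack: float            # L
    W_volume: float           # L
    n_hs_scale: float = 1.0   # half-sarcomeres per circumference (relative)

    @property
    def r(self) -> float:
        return radius_from_volume(self.V_ventricle)

    @property
    def W_thickness(self) -> float:
        return wall_thickness(self.r, self.W_volume)

    @property
    def mid_wall_radius(self) -> float:
        """Radius of the hemisphere enclosing the chamber plus half the wall
        (equals r + W_thickness/2 to first order in thickness/r, but stays
        monotone down to an empty chamber)."""
        return radius_from_volume(self.V_ventricle + 0.5 * self.W_volume)

    def pressure(self, S: float) -> float:
        return ventricular_pressure(S, self.W_thickness, self.r)


def hs_length_from_volume(V: float, geom: VentricleGeometry,
                          L_slack: float) -> float:
    """Half-sarcomere length (nm) of the mid-wall circumferential element.

    Scales the slack length by the ratio of mid-wall circumferences at ``V``
    and at the slack volume; strictly increasing in ``V``.
    """
    if V <= 0.0:
        raise DegenerateGeometryError("ventricular volume must be positive")
    return float(_core.hs_length_from_volume_core(
        V, geom.V_slack, geom.W_volume, L_slack))


@dataclass(frozen=True)
class CirculationParams:
    """Compliances, resistances and total blood volume of the loop."""

    C: dict = field(default_factory=dict)   # L/mmHg per vascular compartment
    R: dict = field(default_factory=dict)   # mmHg s/L per connection
    V_total: float = 5.0                    # L

    def __post_init__(self):
        for name in VASCULAR_COMPARTMENTS:
            if self.C.get(name, 0.0) <= 0.0:
                raise ValueError(f"compliance {name!r} must be positive")
        for name in CONNECTIONS:
            if self.R.get(name, 0.0) <= 0.0:
                raise ValueError(f"resistance {name!r} must be positive")

    def c_vector(self) -> np.ndarray:
        return np.array([self.C[n] for n in VASCULAR_COMPARTMENTS])

    def r_vector(self) -> np.ndarray:
        return np.array([self.R[n] for n in CONNECTIONS])


@dataclass
class CirculationState:
    """Blood volumes (L) of the ventricle plus the five vascular
    compartments, with their parameters."""

    volumes: np.ndarray
    params: CirculationParams

    @classmethod
    def initial(cls, params: CirculationParams, V_ventricle: float
                ) -> "CirculationState":
        """All non-ventricular blood pooled in the veins (the protocol's
        starting condition)."""
        v = np.zeros(6)
        v[0] = V_ventricle
        v[5] = params.V_total - V_ventricle
        return cls(volumes=v, params=params)

    @property
    def V_ventricle(self) -> float:
        return float(self.volumes[0])

    def total(self) -> float:
        return float(self.volumes.sum())

    def validate(self) -> None:
        if np.any(self.volumes < -1e-12):
            raise ValueError("negative compartment volume")


def compartment_pressures(state: CirculationState) -> dict:
    """``P_x = V_x / C_x`` for the five vascular compartments (mmHg).

    The ventricular pressure comes from Laplace's law, not from this rule.
    """
    c = state.params.c_vector()
    p = state.volumes[1:] / c
    return dict(zip(VASCULAR_COMPARTMENTS, p.tolist()))


def flows(pressures: dict, params: CirculationParams,
          P_ventricle: float) -> dict:
    """Ohm's-law flows (L/s) around the loop.

    The aortic-valve and venous-return connections are rectified (one-way
    valves); inter-vascular connections may carry backward flow.
    """
    pvec = np.array([pressures[n] for n in VASCULAR_COMPARTMENTS])
    f = _core.flows_core(P_ventricle, pvec, params.r_vector())
    return dict(zip(CONNECTIONS, f.tolist()))


def update_volumes(state: CirculationState, flow: dict, dt: float,
                   withdrawal_rate: float = 0.0) -> tuple["CirculationState", bool]:
    """Forward-Euler volume update over ``dt`` ms.

    Flows are limited so no compartment is driven negative; withdrawal
    removes blood from the venous compartment only.  Returns the new state
    and a flag marking whether any flow limiting occurred.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    dt_s = dt * 1e-3
    fvec = np.array([flow[n] for n in CONNECTIONS])
    vols = state.volumes.copy()
    fvec, limited = _core.limit_flows_core(fvec, vols, dt_s)
    _core.apply_flows_core(vols, fvec, dt_s, withdrawal_rate)
    new = CirculationState(volumes=vols, params=state.params)
    new.validate()
    return new, bool(limited)
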