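"""Half-sarcomere contraction model (dynamically coupled
myofilaments).

The contractile unit couples a Ca2+-regulated thin filament to a
three-state thick filament:

* **Thin filament** — a fraction ``N_on`` of binding sites is active.
  Activation is driven by Ca2+, deactivation is blocked on sites occupied by
  bound heads, and both directions are cooperatively modulated::

      dN_on/dt = k_on [Ca] (N_overlap - N_on) (1 + k_coop N_on)
               - k_off (N_on - N_bound) (1 + k_coop (N_overlap - N_on))

* **Myosin** — heads populate an OFF (super-relaxed / interacting-heads
  motif) state, an ON state, and a strain-resolved bound force-generating
  (FG) state.  The OFF -> ON rate increases linearly with total wall stress
  (force-dependent recruitment, ``J1 = k_1 (1 + k_force max(F, 0))``), which
  together with the passive-stress contribution gives the model its
  length-dependent activation.  Attachment is Boltzmann-weighted toward zero
  strain; detachment rises steeply (quartically) with strain.  Bound heads
  are advected along the strain axis when the half-sarcomere changes length.

* **Passive stress** — exponential titin-like element,
  ``sigma (exp((l - L_slack)/L) - 1)`` above slack length, zero below.

Stresses are N m^-2 throughout; lengths nm; rates s^-1.  One ATP is counted
per completed cross-bridge cycle (FG -> ON detachment flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core

__all__ = [
    "SarcomereParams", "ThinFilamentState", "MyosinState", "HalfSarcomereState",
    "thin_filament_step", "recruitment_rate", "myosin_step",
    "active_stress", "passive_stress", "run_twitch",
]


@dataclass(frozen=True)
class SarcomereParams:
    """Kinetic and mechanical constants of the half-sarcomere.

    Defaults are the calibrated base values shipped with the package (see
    ``cardioloop/data/default_config.yaml``).
    """

    k_on: float = 2.0e5       # mM^-1 s^-1, thin-filament activation
    k_off: float = 200.0      # s^-1
    k_coop: float = 26.0      # dimensionless cooperativity
    k_1: float = 1.0          # s^-1, OFF -> ON base rate
    k_2: float = 17.5         # s^-1, ON -> OFF
    k_3: float = 105.0        # s^-1 nm^-1, attachment rate density
    k_4_0: float = 120.0      # s^-1, strain-independent detachment
    k_4_1: float = 0.065      # s^-1 nm^-4, strain-dependent detachment
    k_cb: float = 0.001       # N m^-1, cross-bridge stiffness
    x_ps: float = 4.5         # nm, power-stroke displacement
    N_0: float = 2.0e17       # m^-2, head number density
    sigma: float = 1150.0     # N m^-2, passive stress scale
    L: float = 70.0           # nm, passive curvature length constant
    L_slack: float = 900.0    # nm, half-sarcomere slack length
    k_force: float = 2.2e-4   # m^2 N^-1, force-dependent recruitment
    n_overlap: float = 1.0    # maximal available site fraction
    w_ascending: float = 120.0       # nm, ascending-limb length constant
    hsl_full_overlap: float = 1000.0 # nm, plateau starts here
    hsl_desc_start: float = 1100.0   # nm, descending limb starts here
    hsl_desc_end: float = 1500.0     # nm, overlap vanishes again
    hsl_zero_overlap: float = 730.0  # nm, ascending limb reaches zero here

    # strain grid (standard practice: +/-10 nm at 0.5 nm)
    x_min: float = -10.0
    x_max: float = 10.0
    dx: float = 0.5

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_1", "k_2", "k_3", "k_4_0", "k_cb",
                     "x_ps", "N_0", "sigma", "L", "L_slack", "dx"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def vector(self) -> np.ndarray:
        return np.array([
            self.k_on, self.k_off, self.k_coop, self.k_1, self.k_2, self.k_3,
            self.k_4_0, self.k_4_1, self.k_cb, self.x_ps, self.N_0,
            self.sigma, self.L, self.L_slack, self.k_force, self.n_overlap,
            self.w_ascending, self.hsl_full_overlap,
            self.hsl_desc_start, self.hsl_desc_end, self.hsl_zero_overlap,
        ])

    def strain_grid(self) -> np.ndarray:
        n = int(round((self.x_max - self.x_min) / self.dx)) + 1
        return np.linspace(self.x_min, self.x_max, n)


@dataclass
class ThinFilamentState:
    N_on: float = 0.0
    N_bound: float = 0.0

    def validate(self, n_overlap: float = 1.0) -> None:
        if not (0.0 <= self.N_bound <= self.N_on + 1e-9 <= n_overlap + 1e-9):
            raise ValueError(
                f"thin-filament invariant violated: "
                f"N_bound={self.N_bound}, N_on={self.N_on}")


@dataclass
class MyosinState:
    """OFF/ON fractions plus the FG density over cross-bridge strain."""

    M_OFF: float
    M_ON: float
    M_FG: np.ndarray          # density per nm over the strain grid
    x: np.ndarray             # strain grid (nm)

    @classmethod
    def resting(cls, params: SarcomereParams) -> "MyosinState":
        x = params.strain_grid()
        return cls(M_OFF=1.0, M_ON=0.0, M_FG=np.zeros_like(x), x=x)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def bound_fraction(self) -> float:
        return float(self.M_FG.sum() * self.dx)

    def total(self) -> float:
        return float(self.M_OFF + self.M_ON + self.bound_fraction)

    def validate(self) -> None:
        if self.M_OFF < -1e-12 or self.M_ON < -1e-12 or np.any(self.M_FG < -1e-12):
            raise ValueError("negative myosin population")
        if abs(self.total() - 1.0) > 1e-6:
            raise ValueError(f"myosin conservation violated: total={self.total()}")

    def copy(self) -> "MyosinState":
        return MyosinState(self.M_OFF, self.M_ON, self.M_FG.copy(), self.x)


@dataclass
class HalfSarcomereState:
    hs_length: float
    thin: ThinFilamentState
    myosin: MyosinState
    cumulative_atp: float = 0.0

    @classmethod
    def resting(cls, params: SarcomereParams,
                hs_length: float | None = None) -> "HalfSarcomereState":
        return cls(hs_length=params.L_slack if hs_length is None else hs_length,
                   thin=ThinFilamentState(),
                   myosin=MyosinState.resting(params))

    def active_stress(self, params: SarcomereParams) -> float:
        return active_stress(self.myosin, params)

    def passive_stress(self, params: SarcomereParams) -> float:
        return passive_stress(self.hs_length, params)

    def total_stress(self, params: SarcomereParams) -> float:
        return self.active_stress(params) + self.passive_stress(params)


def overlap_fraction(hs_length: float, params: SarcomereParams) -> float:
    """Available thin-filament site fraction at a given half-sarcomere
    length (exponential ascending limb, plateau, linear descending
    limb)."""
    return float(_core.overlap_fraction_core(
        hs_length, params.n_overlap, params.w_ascending,
        params.hsl_full_overlap, params.hsl_desc_start, params.hsl_desc_end,
        params.hsl_zero_overlap))


def recruitment_rate(active_force: float, params: SarcomereParams) -> float:
    """OFF -> ON transition rate J1 (s^-1): linear in force, floored at zero
    force so compression does not de-recruit."""
    return params.k_1 * (1.0 + params.k_force * max(active_force, 0.0))


def passive_stress(hs_length: float, params: SarcomereParams) -> float:
    """Exponential passive (titin-like) stress, zero at and below slack."""
    if hs_length <= 0.0:
        raise ValueError("hs_length must be positive")
    return _core.passive_stress_core(hs_length, params.sigma, params.L,
                                     params.L_slack)


def active_stress(myosin: MyosinState, params: SarcomereParams) -> float:
    """Cross-bridge stress: N_0 k_cb sum_x M_FG(x) (x + x_ps) dx."""
    return _core.active_stress_core(myosin.M_FG, myosin.x, myosin.dx,
                                    params.k_cb, params.x_ps, params.N_0)


def thin_filament_step(thin: ThinFilamentState, Ca: float, hs_length: float,
                       params: SarcomereParams, dt: float) -> ThinFilamentState:
    """Advance thin-filament activation by ``dt`` ms at Ca (mM).

    ``N_on`` cannot fall below the bound-site fraction and cannot exceed the
    available overlap fraction.
    """
    if Ca < 0.0:
        raise ValueError("Ca must be non-negative")
    nov = overlap_fraction(hs_length, params)
    d = params.k_on * Ca * (nov - thin.N_on) * (1.0 + params.k_coop * thin.N_on) \
        - params.k_off * (thin.N_on - thin.N_bound) \
        * (1.0 + params.k_coop * (nov - thin.N_on))
    n_on = thin.N_on + dt * 1e-3 * d
    n_on = min(max(n_on, thin.N_bound), max(nov, thin.N_bound))
    out = ThinFilamentState(N_on=n_on, N_bound=thin.N_bound)
    out.validate(max(nov, thin.N_bound))
    return out


def myosin_step(myosin: MyosinState, thin: ThinFilamentState,
                params: SarcomereParams, dt: float,
                delta_hsl: float = 0.0, hs_length: float | None = None,
                n_substeps: int = 1) -> tuple[MyosinState, ThinFilamentState, float]:
    """Advance the myosin populations by ``dt`` ms.

    Applies (i) strain advection of bound heads by ``delta_hsl`` nm,
    (ii) force-dependent OFF<->ON exchange, (iii) strain-weighted attachment
    into available sites, (iv) strain-dependent detachment.  Returns the new
    myosin state, the thin-filament state with updated ``N_bound``/``N_on``,
    and the ATP consumed (per head) during the step.
    """
    out = myosin.copy()
    hsl = params.L_slack if hs_length is None else hs_length
    fg, lost = _core.advect_fg(out.M_FG, out.x, out.dx, delta_hsl)
    out.M_FG = fg
    out.M_ON += lost
    n_on = thin.N_on
    atp = 0.0
    sub = dt * 1e-3 / n_substeps
    sp = params.vector()
    for _ in range(n_substeps):
        # N_on is an input here (thin-filament kinetics advance separately);
        # only its floor moves with the freshly bound heads
        n_on, out.M_OFF, out.M_ON, datp = _core.sarc_substep(
            n_on, out.M_OFF, out.M_ON, out.M_FG, out.x, out.dx,
            0.0, hsl, sp, sub, True)
        atp += datp
        n_on = max(thin.N_on, out.bound_fraction)
    out.validate()
    new_thin = ThinFilamentState(N_on=max(n_on, out.bound_fraction),
                                 N_bound=out.bound_fraction)
    return out, new_thin, atp


def run_twitch(ca_trace: np.ndarray, hsl_trace: np.ndarray,
               params: SarcomereParams, dt: float = 1.0,
               n_substeps: int = 5) -> pd.DataFrame:
    """Cell-level twitch protocol: prescribed Ca (mM) and half-sarcomere
    length (nm) traces, sampled every ``dt`` ms.

    Returns a tidy DataFrame of the stress and state trajectories.  Used for
    isolated-myofilament experiments and by the test suite.
    """
    ca_trace = np.asarray(ca_trace, dtype=float)
    hsl_trace = np.asarray(hsl_trace, dtype=float)
    if ca_trace.shape != hsl_trace.shape:
        raise ValueError("Ca and length traces must have equal length")
    sp = params.vector()
    x = params.strain_grid()
    dx = params.dx
    n = ca_trace.size
    n_on = 0.0
    m_off, m_on = 1.0, 0.0
    fg = np.zeros_like(x)
    atp_cum = 0.0
    rows = np.zeros((n, 10))
    hsl_prev = hsl_trace[0]
    sub = dt * 1e-3 / n_substeps
    for i in range(n):
        dhsl = hsl_trace[i] - hsl_prev
        hsl_prev = hsl_trace[i]
        fg, lost = _core.advect_fg(fg, x, dx, dhsl)
        m_on += lost
        for _ in range(n_substeps):
            n_on, m_off, m_on, datp = _core.sarc_substep(
                n_on, m_off, m_on, fg, x, dx, ca_trace[i], hsl_trace[i],
                sp, sub)
            atp_cum += datp
        s_act = _core.active_stress_core(fg, x, dx, params.k_cb, params.x_ps,
                                         params.N_0)
        s_pas = _core.passive_stress_core(hsl_trace[i], params.sigma,
                                          params.L, params.L_slack)
        rows[i] = (i * dt * 1e-3, ca_trace[i], hsl_trace[i], n_on,
                   fg.sum() * dx, m_off, m_on, s_act, s_pas, atp_cum)
    df = pd.DataFrame(rows, columns=[
        "time", "Ca", "hs_length", "N_on", "N_bound", "M_OFF", "M_ON",
        "active_stress", "passive_stress", "atp_cum"])
    df["total_stress"] = df.active_stress + df.passive_stress
    return df
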