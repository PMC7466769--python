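"""Pressure-volume analytics: per-beat system-level properties, ESPVR
estimators, parameter sweeps and the relative-sensitivity matrix.

The 12 system-level properties extracted from a run are: maximum and
minimum ventricular pressure, maximum and minimum ventricular volume,
stroke volume, ejection fraction, cardiac output, stroke work, myosin
ATPase per beat, efficiency (stroke work per ATP), the ESPVR slope, and
maximum aortic pressure.

Relative sensitivity of a property to a parameter is the slope at
multiplier 1 of a 5th-order polynomial fitted to the property across a
0.1-10x multiplier sweep, normalized by the property value there:
``p'(1) / p(1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import ConfigDocument, PARAM_GROUPS
from .engine import Timecourse, run_simulation
from .membrane_ep import NumericalFailure

__all__ = [
    "BeatMetrics", "SensitivityMatrix", "extract_beat_metrics",
    "system_properties", "espvr_multibeat", "espvr_single_beat",
    "parameter_sweep", "relative_sensitivity", "sensitivity_matrix",
    "ejection_force_drop", "beats_to_steady_state", "PROPERTY_NAMES",
]

PROPERTY_NAMES = [
    "max_ventricular_pressure", "min_ventricular_pressure",
    "max_ventricular_volume", "min_ventricular_volume",
    "stroke_volume", "ejection_fraction", "cardiac_output",
    "stroke_work", "myosin_atpase", "efficiency", "espvr",
    "max_aortic_pressure",
]


@dataclass
class BeatMetrics:
    """The 12 system-level properties of a steady-state beat."""

    max_ventricular_pressure: float   # mmHg
    min_ventricular_pressure: float   # mmHg
    max_ventricular_volume: float     # L
    min_ventricular_volume: float     # L
    stroke_volume: float              # L
    ejection_fraction: float
    cardiac_output: float             # L/min
    stroke_work: float                # mmHg L
    myosin_atpase: float              # ATP per head per beat
    efficiency: float                 # stroke work / ATP (model units)
    espvr: float                      # mmHg/L (nan when not estimated)
    max_aortic_pressure: float        # mmHg
    steady: bool = True               # False flags beat-over-beat drift > 1%

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name)
                          for f in dc_fields(self) if f.name != "steady"})


def _loop_area(P: np.ndarray, V: np.ndarray) -> float:
    """Stroke work as the PV-loop area (mmHg L), positive for a normally
    oriented (counterclockwise in the V-P plane) loop."""
    dV = np.diff(V)
    return float(-np.sum(0.5 * (P[:-1] + P[1:]) * dV))


def extract_beat_metrics(timecourse: Timecourse, beat: int,
                         espvr: float = np.nan) -> BeatMetrics:
    """Metrics over one stimulus-to-stimulus window (0-based beat index).

    A warning flag (``steady=False``) is set when the previous beat's peak
    pressure or end-diastolic volume differs by more than 1%.
    """
    b = timecourse.beat_slice(beat)
    P = b["P_ventricle"].to_numpy()
    V = b["V_ventricle"].to_numpy()
    vmax = float(V.max())
    vmin = float(V.min())
    sv = vmax - vmin
    rate_hz = timecourse.config.protocol.rate_hz
    atp = float(b["atp_cum"].iloc[-1] - b["atp_cum"].iloc[0])
    sw = _loop_area(P, V)

    steady = True
    if beat > 0:
        prev = timecourse.beat_slice(beat - 1)
        for col in ("P_ventricle", "V_ventricle"):
            a = prev[col].max()
            c = b[col].max()
            if a != 0 and abs(c - a) / abs(a) > 0.01:
                steady = False
    if not steady:
        warnings.warn(f"beat {beat} is not at periodic steady state",
                      stacklevel=2)

    return BeatMetrics(
        max_ventricular_pressure=float(P.max()),
        min_ventricular_pressure=float(P.min()),
        max_ventricular_volume=vmax,
        min_ventricular_volume=vmin,
        stroke_volume=sv,
        ejection_fraction=sv / vmax if vmax > 0 else np.nan,
        cardiac_output=sv * rate_hz * 60.0,
        stroke_work=sw,
        myosin_atpase=atp,
        efficiency=sw / atp if atp > 0 else np.nan,
        espvr=espvr,
        max_aortic_pressure=float(b["P_aorta"].max()),
        steady=steady,
    )


def espvr_multibeat(timecourse: Timecourse,
                    beat_range: tuple[int, int] | None = None) -> float:
    """ESPVR slope (mmHg/L) from the preload-reduction beats.

    The end-systolic point of each beat is the sample maximizing P/V (the
    top-left corner of its PV loop); the slope is the ordinary
    least-squares line through those corner points.
    """
    if beat_range is None:
        proto = timecourse.config.protocol
        beat_range = (proto.withdrawal_start_beat - 1,
                      proto.withdrawal_end_beat - 1)
    lo, hi = beat_range
    if hi - lo + 1 < 3:
        raise ValueError("need at least 3 beats for the ESPVR regression")
    pts_v, pts_p = [], []
    for beat in range(lo, hi + 1):
        b = timecourse.beat_slice(beat)
        P = b["P_ventricle"].to_numpy()
        V = b["V_ventricle"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(V > 0, P / V, -np.inf)
        k = int(np.argmax(ratio))
        pts_v.append(V[k])
        pts_p.append(P[k])
    slope, _ = np.polyfit(pts_v, pts_p, 1)
    return float(slope)


class SingleBeatEstimationError(RuntimeError):
    pass


def espvr_single_beat(beat: pd.DataFrame, rate_hz: float = 1.0) -> float:
    """Single-beat ESPVR estimate via sinusoidal extrapolation.

    Fits ``P(t) = Pm + Pa sin(w t + phi)`` to the isovolumic contraction and
    relaxation segments of the beat, extrapolates the peak isovolumic
    pressure ``P_max,iso = Pm + Pa`` the ventricle would have reached with
    both valves shut, and returns
    ``(P_max,iso - P_es) / (V_ed - V_es)``.
    """
    t = beat["time"].to_numpy()
    t = t - t[0]
    P = beat["P_ventricle"].to_numpy()
    V = beat["V_ventricle"].to_numpy()
    fav = beat["flow_aortic_valve"].to_numpy()
    fvr = beat["flow_venous_return"].to_numpy()

    eject = np.flatnonzero(fav > 0)
    if eject.size == 0:
        # fully isovolumic beat: the observed peak is the isovolumic peak
        p_max_iso = float(P.max())
        idx_es = int(np.argmax(P))
    else:
        i_open, i_close = eject[0], eject[-1]
        # isovolumic phases: both valves shut (mitral closed before ejection,
        # reopening after it)
        both_shut = (fav == 0) & (fvr == 0)
        ivc = np.flatnonzero(both_shut[:i_open])
        after = np.flatnonzero(fvr[i_close:] > 0)
        i_mitral = i_close + (after[0] if after.size else len(P) - 1 - i_close)
        ivr = i_close + 1 + np.flatnonzero(both_shut[i_close + 1:i_mitral])
        idx = np.concatenate([ivc, ivr]).astype(int)
        if ivc.size < 3 or ivr.size < 3:
            raise SingleBeatEstimationError(
                "too few isovolumic samples for the sinusoid fit")

        # the sine's half-period spans the isovolumic envelope; the two
        # segments carry equal total weight so the long relaxation tail
        # cannot dominate the fit
        t0 = t[ivc[0]]
        half_period = max(t[ivr[-1]] - t0, 0.15)
        omega = np.pi / half_period
        sig = np.concatenate([np.full(ivc.size, 1.0 / ivc.size),
                              np.full(ivr.size, 1.0 / ivr.size)])

        def model(tt, pm, pa, phi):
            return pm + pa * np.sin(omega * (tt - t0) + phi)

        p0 = [0.5 * P.max(), 0.6 * P.max(), -0.3]
        try:
            popt, _ = curve_fit(model, t[idx], P[idx], p0=p0, sigma=sig,
                                maxfev=20000)
        except RuntimeError as err:
            raise SingleBeatEstimationError(
                f"sinusoid fit did not converge: {err}") from err
        pm, pa = popt[0], abs(popt[1])
        p_max_iso = pm + pa
        if not np.isfinite(p_max_iso) or p_max_iso < P.max():
            p_max_iso = float(P.max())
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(V > 0, P / V, -np.inf)
        idx_es = int(np.argmax(ratio))

    p_es = P[idx_es]
    v_es = float(V.min())
    v_ed = float(V.max())
    if v_ed - v_es <= 0:
        raise SingleBeatEstimationError("beat has no stroke volume")
    return float((p_max_iso - p_es) / (v_ed - v_es))


def ejection_force_drop(timecourse: Timecourse, beat: int = 8) -> float:
    """Fractional fall of half-sarcomere stress across the ejection phase
    of a beat: 1 - S(end of ejection) / max S(during ejection)."""
    b = timecourse.beat_slice(beat)
    fav = b["flow_aortic_valve"].to_numpy()
    S = b["total_stress"].to_numpy()
    eject = np.flatnonzero(fav > 0)
    if eject.size < 2:
        return 0.0
    s_ej = S[eject]
    return float(1.0 - s_ej[-1] / s_ej.max())


def beats_to_steady_state(timecourse: Timecourse, reference_beat: int = 8,
                          tol: float = 0.01) -> int:
    """Number of beats (1-based) to reach periodic steady state.

    The first beat whose peak pressure and end-diastolic volume are both
    within ``tol`` of the reference (last pre-withdrawal) beat.
    """
    ref = timecourse.beat_slice(reference_beat)
    ref_p = ref["P_ventricle"].max()
    ref_v = ref["V_ventricle"].max()
    for beat in range(reference_beat + 1):
        b = timecourse.beat_slice(beat)
        if (abs(b["P_ventricle"].max() - ref_p) <= tol * ref_p
                and abs(b["V_ventricle"].max() - ref_v) <= tol * ref_v):
            return beat + 1
    return reference_beat + 1


def system_properties(config: ConfigDocument | None = None,
                      timecourse: Timecourse | None = None,
                      steady_beat: int = 8) -> BeatMetrics:
    """Run the full protocol (or reuse a run) and extract the 12 properties,
    including the ESPVR from the withdrawal window."""
    if timecourse is None:
        timecourse = run_simulation(config)
    espvr = espvr_multibeat(timecourse)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_beat_metrics(timecourse, steady_beat, espvr=espvr)


def parameter_sweep(config: ConfigDocument, parameter_name: str,
                    multipliers=None) -> pd.DataFrame:
    """Run the full protocol at each multiplier of one parameter.

    Returns a tidy table (one row per multiplier) of the 12 properties plus
    a status column; failed runs are flagged, not dropped.
    """
    if multipliers is None:
        multipliers = config.sweeps.multipliers
    rows = []
    for m in multipliers:
        cfg = config.with_multiplier(parameter_name, m)
        row = {"parameter": parameter_name, "multiplier": m}
        try:
            metrics = system_properties(cfg)
            row.update(metrics.as_series().to_dict())
            row["status"] = "ok" if metrics.steady else "not_steady"
        except (NumericalFailure, ValueError) as err:
            row.update({name: np.nan for name in PROPERTY_NAMES})
            row["status"] = f"failed: {err}"
        rows.append(row)
    return pd.DataFrame(rows)


def relative_sensitivity(sweep_table: pd.DataFrame,
                         property_name: str) -> float:
    """``p'(1)/p(1)`` of the 5th-order polynomial fit of a property against
    the (linear) multiplier."""
    ok = sweep_table[sweep_table["status"].str.startswith(("ok", "not_steady"))]
    ok = ok.dropna(subset=[property_name])
    if len(ok) < 7 or 1.0 not in set(np.round(ok["multiplier"], 12)):
        raise ValueError("need >= 7 valid sweep points including multiplier 1")
    x = ok["multiplier"].to_numpy(float)
    y = ok[property_name].to_numpy(float)
    poly = np.polynomial.Polynomial.fit(x, y, 5)
    p1 = poly(1.0)
    if abs(p1) < 1e-12:
        return np.nan  # undefined-sensitivity flag
    return float(poly.deriv()(1.0) / p1)


@dataclass
class SensitivityMatrix:
    """Relative sensitivities for every (parameter, property) pair."""

    values: pd.DataFrame            # index = parameters, columns = properties
    groups: dict                    # parameter -> group name

    @property
    def property_mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0).sort_values(ascending=False)

    @property
    def parameter_mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=1).sort_values(ascending=False)

    def top_parameter_per_group(self) -> dict:
        out = {}
        means = self.values.abs().mean(axis=1)
        for group in PARAM_GROUPS:
            members = [p for p in self.values.index
                       if self.groups.get(p) == group]
            if members:
                out[group] = means.loc[members].idxmax()
        return out

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def plot_heatmap(self, path=None):
        """Red/blue heat-map with mean-absolute-sensitivity bars."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = self.values
        lim = np.nanmax(np.abs(vals.to_numpy())) or 1.0
        fig, axes = plt.subplots(
            2, 2, figsize=(11, 8), width_ratios=[5, 1], height_ratios=[1, 4],
            sharex="col", sharey="row")
        ax = axes[1, 0]
        im = ax.imshow(vals.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim,
                       aspect="auto")
        ax.set_xticks(range(len(vals.columns)))
        ax.set_xticklabels(vals.columns, rotation=90)
        ax.set_yticks(range(len(vals.index)))
        ax.set_yticklabels(vals.index)
        axes[0, 0].bar(range(len(vals.columns)),
                       vals.abs().mean(axis=0).to_numpy(), color="0.6")
        axes[0, 0].set_ylabel("mean |sens|")
        axes[1, 1].barh(range(len(vals.index)),
                        vals.abs().mean(axis=1).to_numpy(), color="0.6")
        axes[1, 1].invert_yaxis()
        axes[0, 1].axis("off")
        fig.colorbar(im, ax=axes[1, 0], shrink=0.8, label="relative sensitivity")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def sensitivity_matrix(config: ConfigDocument | None = None,
                       parameter_list=None, multipliers=None,
                       sweep_tables: dict | None = None) -> SensitivityMatrix:
    """Full sweep of every parameter and assembly of the sensitivity matrix.

    ``sweep_tables`` may carry pre-computed :func:`parameter_sweep` outputs
    (keyed by parameter) to avoid re-running.
    """
    if config is None:
        config = ConfigDocument()
    if parameter_list is None:
        parameter_list = config.sweeps.parameters
    if multipliers is None:
        multipliers = config.sweeps.multipliers
    mat = {}
    for name in parameter_list:
        if sweep_tables is not None and name in sweep_tables:
            table = sweep_tables[name]
        else:
            table = parameter_sweep(config, name, multipliers)
        row = {}
        for prop in PROPERTY_NAMES:
            try:
                row[prop] = relative_sensitivity(table, prop)
            except ValueError:
                row[prop] = np.nan
        mat[name] = row
    values = pd.DataFrame(mat).T.loc[list(parameter_list), PROPERTY_NAMES]
    groups = {name: config.group_of(name) for name in parameter_list}
    return SensitivityMatrix(values=values, groups=groups)
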