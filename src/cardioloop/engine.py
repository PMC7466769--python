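"""Time-stepping orchestrator for the closed-loop simulation.

Each outer time step (1 ms by default) advances the system with one-way
coupling: the paced myocyte model produces the free cytosolic Ca2+
concentration; wall stress from the half-sarcomere at the current chamber
volume sets the ventricular pressure via Laplace's law; valve and Ohm's-law
flows update the compartment volumes; and the half-sarcomere is advanced
with the length change implied by the new ventricular volume.  Isovolumic
phases emerge naturally whenever both valves carry zero flow.

The standard protocol runs 17 beats at 1 Hz from a pre-paced myocyte, with
the ventricle initially filled to 150% of its slack volume and the rest of
the blood pooled in the veins; 60% of the total blood volume is withdrawn
from the venous compartment at a constant rate across beats 10-15 to probe
the preload dependence (the basis of the ESPVR estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _core
from .config import ConfigDocument
from .membrane_ep import EpState, NumericalFailure, prepaced_state_cached

__all__ = ["Timecourse", "run_simulation", "generate_baseline_fixtures"]


@dataclass
class Timecourse:
    """Uniformly sampled record of a simulation.

    ``data`` has one row per outer step (column names in
    ``cardioloop._core.LOG_COLUMNS``); beats are delimited by the stimulus
    times.
    """

    data: pd.DataFrame
    config: ConfigDocument

    @property
    def dt_ms(self) -> float:
        return self.config.numerics.dt_ms

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.config.protocol.rate_hz

    @property
    def n_beats(self) -> int:
        return self.config.protocol.n_beats

    def beat_boundaries(self) -> np.ndarray:
        """Row indices at which each beat starts (stimulus onsets)."""
        step = int(round(self.period_ms / self.dt_ms))
        return np.arange(self.n_beats) * step

    def beat_slice(self, beat: int) -> pd.DataFrame:
        """Samples of one beat (0-based index), stimulus to stimulus."""
        if not 0 <= beat < self.n_beats:
            raise IndexError(f"beat {beat} outside 0..{self.n_beats - 1}")
        step = int(round(self.period_ms / self.dt_ms))
        lo = beat * step
        return self.data.iloc[lo:lo + step + 1]

def _withdrawal_window_ms(config: ConfigDocument) -> tuple[float, float]:
    proto = config.protocol
    period = 1000.0 / proto.rate_hz
    return ((proto.withdrawal_start_beat - 1) * period,
            (proto.withdrawal_end_beat - 1) * period)


def run_simulation(config: ConfigDocument | None = None) -> Timecourse:
    """Run the configured closed-loop protocol and return the Timecourse."""
    if config is None:
        config = ConfigDocument()
    proto = config.protocol
    num = config.numerics

    ep_params = config.ep_params()
    ep0 = prepaced_state_cached(ep_params, n_beats=num.ep_prepace_beats,
                                rate=proto.rate_hz)

    sp = config.sarcomere_params()
    circ = config.circulation_params()
    cp = np.concatenate([
        [config.ventricle.V_slack.effective,
         config.ventricle.W_volume.effective],
        circ.c_vector(), circ.r_vector(),
        [circ.V_total, config.ventricle.V_residual.effective],
    ])
    wd_start, wd_end = _withdrawal_window_ms(config)
    period = 1000.0 / proto.rate_hz

    log, status = _core.run_coupled(
        ep0.values, ep_params.vector(), sp.vector(), cp, sp.strain_grid(),
        proto.n_beats, period, proto.stim_duration_ms, proto.stim_amplitude,
        proto.initial_fill_fraction, proto.withdrawal_fraction,
        wd_start, wd_end, num.dt_ms, num.sarcomere_substeps,
        num.hemo_substeps)
    if status != 0:
        t_fail = (status - 1) * num.dt_ms * 1e-3
        raise NumericalFailure(
            f"simulation became non-finite at t = {t_fail:.3f} s")

    df = pd.DataFrame(log, columns=_core.LOG_COLUMNS)
    return Timecourse(data=df, config=config)


def generate_baseline_fixtures(config: ConfigDocument | None = None,
                               directory: str | Path = "fixtures"
                               ) -> dict[str, Path]:
    """Write the canonical baseline Timecourse and a steady-state-beat
    extract as regression fixtures (CSV with a config-hash header)."""
    if config is None:
        config = ConfigDocument()
    tc = run_simulation(config)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash: {config.content_hash()}\n"

    full = directory / "baseline_timecourse.csv"
    with open(full, "w") as fh:
        fh.write(header)
        tc.data.to_csv(fh, index=False)

    beat = tc.beat_slice(8)  # 9th beat: steady state, pre-withdrawal
    extract = directory / "baseline_steady_beat.csv"
    with open(extract, "w") as fh:
        fh.write(header)
        beat.to_csv(fh, index=False)
    return {"timecourse": full, "steady_beat": extract}
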