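"""Parameters of the synthetic session generator.

The generator produces 3-state sleep sessions from a pressure-coupled
semi-Markov model on the 2.5 s epoch grid:

* wake (W), NREM (N) and REM (R) exchange via per-epoch hazards;
* a latent REM pressure accumulates at rate ``rem_pressure_gain`` (units/s)
  during NREM, dissipates at ``rem_dissipation`` (units/s) during REM
  (floored at zero), and is frozen during wake;
* the N->R hazard is a saturating, monotone logistic function of
  pressure (see :meth:`GeneratorParams.n2r_hazard`), anchored so that
  zero pressure means a zero REM-entry hazard and the hazard stays
  below ``h_n2r_max``.

Laser effects are hazard multipliers, so the null experiment (all
multipliers 1) shares the exact code path with the effect experiment.

Default hazards and pressure constants were chosen so that, in the light
phase the generator emulates, REM episodes last about a minute and recur
every 10-15 minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


def _default_eeg_mix() -> dict:
    # per-state amplitudes of the delta (1-4 Hz), theta (6-12 Hz) and
    # broadband components of the synthetic EEG
    return {
        "N": {"delta": 1.0, "theta": 0.25, "broad": 0.15},
        "R": {"delta": 0.15, "theta": 0.9, "broad": 0.15},
        "W": {"delta": 0.25, "theta": 0.45, "broad": 0.5},
    }


def _default_emg_amp() -> dict:
    return {"W": 1.0, "N": 0.15, "R": 0.05}


def _default_unit_rates() -> dict:
    # REM-off profile: active in wake/NREM, nearly silent in REM
    return {"W": 8.0, "N": 6.0, "R": 1.0}


def _default_laser_mult() -> dict:
    # direction of the optogenetic effect: REM entry and maintenance
    # suppressed, NREM stabilised
    return {"NR": 0.1, "NW": 0.5, "RW": 2.0, "WN": 2.0}


@dataclass
class GeneratorParams:
    """All knobs of the synthetic generator.  Units in field comments."""

    epoch_s: float = 2.5

    # base per-epoch transition hazards
    h_w2n: float = 0.05
    h_n2w: float = 0.012
    h_r2w: float = 0.03
    h_r2n: float = 0.002

    # REM pressure model
    pressure_coupled: bool = True
    h_n2r_max: float = 0.08          # hazard ceiling per epoch
    pressure_midpoint: float = 6.0   # pressure units; logistic midpoint
    pressure_halfsat: float = 0.8    # pressure units; logistic scale
    h_n2r_fixed: float = 0.01        # used when pressure_coupled is False
    rem_pressure_gain: float = 0.007  # pressure units per s of NREM
    rem_dissipation: float = 0.14     # pressure units per s of REM
    initial_pressure: float = 0.0

    # EEG / EMG synthesis
    eeg_mix: dict = field(default_factory=_default_eeg_mix)
    emg_amp: dict = field(default_factory=_default_emg_amp)
    eeg_noise_amp: float = 0.15      # state-independent broadband floor
    emg_noise_amp: float = 0.02
    crossfade_s: float = 0.5

    # single-unit model (REM-off profile by default)
    unit_rates: dict = field(default_factory=_default_unit_rates)
    unit_drift_per_min: float = 0.05   # gain lost per min of NREM
    unit_reset_per_s: float = 0.005    # gain regained per s of REM
    unit_gain_floor: float = 0.2

    # laser protocols
    laser_mult: dict = field(default_factory=_default_laser_mult)
    laser_dur_s: float = 300.0
    laser_hz: float = 20.0
    iti_min_s: float = 900.0         # 15 min
    iti_max_s: float = 1500.0        # 25 min
    closed_gate_p: float = 0.5

    # calcium movie
    frame_hz: float = 10.0
    ca_rise_s: float = 0.1
    ca_decay_s: float = 1.0
    ca_event_hz: float = 0.2
    neuropil_gain: float = 0.55
    bleach_per_min: float = 0.005    # fractional loss per minute
    jitter_px: int = 3
    ca_noise_sd: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if not math.isfinite(v):
                    raise ValueError(f"parameter {f.name!r} is not finite")
            elif isinstance(v, dict):
                for k, sub in v.items():
                    vals = sub.values() if isinstance(sub, dict) else [sub]
                    for x in vals:
                        if not math.isfinite(x):
                            raise ValueError(
                                f"parameter {f.name!r}[{k!r}] is not finite"
                            )
        if self.epoch_s <= 0:
            raise ValueError("parameter 'epoch_s' must be positive")
        for name in ("h_w2n", "h_n2w", "h_r2w", "h_r2n", "h_n2r_max",
                     "h_n2r_fixed"):
            h = getattr(self, name)
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hazard {name!r} must lie in [0, 1]")
        for name in ("rem_pressure_gain", "rem_dissipation",
                     "initial_pressure"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0")
        if any(r < 0 for r in self.unit_rates.values()):
            raise ValueError("parameter 'unit_rates' must be non-negative")
        if not 0.0 <= self.closed_gate_p <= 1.0:
            raise ValueError("parameter 'closed_gate_p' must lie in [0, 1]")

    def n2r_hazard(self, pressure: float) -> float:
        """Pressure -> N->R hazard: logistic saturation anchored at zero.

        A logistic in pressure, centred at ``pressure_midpoint`` with
        scale ``pressure_halfsat``, shifted and rescaled so that
        h(0) = 0 exactly and h(inf) = ``h_n2r_max``.  Monotone and
        bounded, with the low-pressure refractory behaviour the
        homeostatic model requires.
        """
        if not self.pressure_coupled:
            return self.h_n2r_fixed
        if pressure <= 0:
            return 0.0
        s0 = 1.0 / (1.0 + math.exp(self.pressure_midpoint
                                   / self.pressure_halfsat))
        s = 1.0 / (1.0 + math.exp(-(pressure - self.pressure_midpoint)
                                  / self.pressure_halfsat))
        return self.h_n2r_max * (s - s0) / (1.0 - s0)
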