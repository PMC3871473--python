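"""Synthetic hemodynamics: elastance ventricle + 3-element Windkessel.

Generates the five measured channels (ECG, aortic pressure, aortic flow,
LV pressure, LV volume) at 1 kHz under six experimental conditions, plus
a measurement model (conductance-catheter volume gain/offset, additive
channel noise) so that downstream gain calibration has something to do.

The continuous model has two states: LV volume ``v_lv`` and Windkessel
(arterial) pressure ``p_art``::

    p_lv  = E(t) (v_lv - v0)
    q_ao  = max(0, p_lv - p_art) / (r_valve_ao + r_char)   # aortic valve
    p_ao  = p_art + q_ao r_char                            # measured site
    q_mit = max(0, p_ven - p_lv) / r_mitral                # mitral inflow
    q_reg = regurg_frac max(0, p_lv - p_ven) / r_mitral    # insufficiency
    dv_lv/dt  = q_mit - q_ao - q_reg
    c_art dp_art/dt = q_ao - (p_art - P_VEN_REF) / r_periph

Integration is fixed-step RK4 at the sampling rate; warm-up cycles are
discarded so records are periodic steady state.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

from .errors import ConfigError, SimulationError
from .signal_io import WaveformRecord

#: Downstream reference pressure of the Windkessel drain (mmHg).
P_VEN_REF = 5.0

#: Fraction of the activation window at which elastance peaks.
_PEAK_FRAC = 0.55


@dataclasses.dataclass(frozen=True)
class VentricleParams:
    """Time-varying-elastance left ventricle.

    e_max/e_min in mmHg/mL, v0 (unstressed volume) in mL, t_sys_frac the
    fraction of the cycle occupied by systolic activation.
    """

    e_max: float
    e_min: float
    v0: float
    t_sys_frac: float

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise ConfigError(f"need e_max > e_min > 0, got e_max={self.e_max}, e_min={self.e_min}")
        if self.v0 < 0:
            raise ConfigError(f"v0 must be >= 0, got {self.v0}")
        if not (0 < self.t_sys_frac < 1):
            raise ConfigError(f"t_sys_frac must be in (0, 1), got {self.t_sys_frac}")


@dataclasses.dataclass(frozen=True)
class CirculationParams:
    """Valves and 3-element Windkessel load (resistances mmHg.s/mL)."""

    r_valve_ao: float
    r_char: float
    r_periph: float
    c_art: float
    p_ven: float
    r_mitral: float
    regurg_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_valve_ao", "r_char", "r_periph", "r_mitral"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.c_art <= 0:
            raise ConfigError(f"c_art must be > 0, got {self.c_art}")
        if self.p_ven < 0:
            raise ConfigError(f"p_ven must be >= 0, got {self.p_ven}")
        if not (0 <= self.regurg_frac < 1):
            raise ConfigError(f"regurg_frac must be in [0, 1), got {self.regurg_frac}")


@dataclasses.dataclass(frozen=True)
class AnimalSpec:
    """One synthetic animal: physiology plus its measurement-chain errors."""

    animal_id: str
    heart_rate: float
    ventricle: VentricleParams
    circulation: CirculationParams
    alpha_true: float = 1.0
    volume_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (50 <= self.heart_rate <= 200):
            raise ConfigError(f"heart_rate must be in [50, 200], got {self.heart_rate}")
        if not (0.7 <= self.alpha_true <= 1.5):
            raise ConfigError(f"alpha_true must be in [0.7, 1.5], got {self.alpha_true}")


#: Default parameter multipliers per experimental condition.  These are
#: calibration targets tuned once so the >=20% CO-reduction bound and the
#: ~15% oscillatory-power fraction hold with the species defaults below.
CONDITION_MULTIPLIERS: dict[str, dict[str, float]] = {
    "baseline": {},
    "preload_reduced": {"p_ven": 0.65},
    "afterload_increased": {"r_periph": 1.6},
    "dobutamine": {"e_max": 1.5, "heart_rate": 1.15, "r_periph": 0.9},
    "nitroprusside": {"r_periph": 0.65, "p_ven": 0.85},
    "metoprolol": {"e_max": 0.7, "heart_rate": 0.85},
}

CONDITION_NAMES = tuple(CONDITION_MULTIPLIERS)


@dataclasses.dataclass(frozen=True)
class ConditionSpec:
    """A named intervention expressed as parameter scale factors."""

    name: str
    multipliers: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ConfigError(f"unknown condition {self.name!r}; expected one of {CONDITION_NAMES}")
        for key, value in self.multipliers.items():
            if value <= 0:
                raise ConfigError(f"multiplier for {key!r} must be > 0, got {value}")

    @classmethod
    def default(cls, name: str) -> "ConditionSpec":
        if name not in CONDITION_MULTIPLIERS:
            raise ConfigError(f"unknown condition {name!r}; expected one of {CONDITION_NAMES}")
        return cls(name=name, multipliers=dict(CONDITION_MULTIPLIERS[name]))


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Sampling, record length, warm-up and measurement-noise settings."""

    fs: float = 1000.0
    n_cycles: int = 10
    warmup_cycles: int = 15
    seed: int = 0
    noise_ecg: float = 0.05
    noise_p_ao: float = 0.8
    noise_q_ao: float = 0.08
    noise_p_lv: float = 0.8
    noise_v_lv: float = 1.0

    def __post_init__(self) -> None:
        if self.fs < 200:
            raise ConfigError(f"fs must be >= 200 Hz, got {self.fs}")
        if self.n_cycles < 1:
            raise ConfigError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.warmup_cycles < 5:
            raise ConfigError(f"warmup_cycles must be >= 5, got {self.warmup_cycles}")
        for name in ("noise_ecg", "noise_p_ao", "noise_q_ao", "noise_p_lv", "noise_v_lv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def noise_free(self) -> "SimConfig":
        return dataclasses.replace(
            self, noise_ecg=0.0, noise_p_ao=0.0, noise_q_ao=0.0, noise_p_lv=0.0, noise_v_lv=0.0
        )


def default_animal(animal_id: str = "A") -> AnimalSpec:
    """Species defaults for a ~25-30 kg pig under general anesthesia."""
    return AnimalSpec(
        animal_id=animal_id,
        heart_rate=95.0,
        ventricle=VentricleParams(e_max=3.0, e_min=0.10, v0=8.0, t_sys_frac=0.46),
        circulation=CirculationParams(
            r_valve_ao=0.010,
            r_char=0.035,
            r_periph=1.15,
            c_art=2.80,
            p_ven=9.0,
            r_mitral=0.020,
            regurg_frac=0.0,
        ),
        alpha_true=1.0,
        volume_offset=0.0,
    )


def sample_animals(n: int, seed: int) -> list[AnimalSpec]:
    """Draw ``n`` animals with seeded lognormal jitter (SD ~10%) around the
    species defaults, plus a conductance gain alpha_true and offset."""
    rng = np.random.default_rng(seed)
    base = default_animal()
    animals = []
    for i in range(n):
        animal_id = chr(ord("A") + i) if i < 26 else f"Z{i}"
        jit = lambda sd: float(rng.lognormal(mean=0.0, sigma=sd))  # noqa: E731
        hr = float(np.clip(base.heart_rate * jit(0.06), 60.0, 160.0))
        alpha = float(np.clip(rng.lognormal(mean=0.0, sigma=0.10), 0.75, 1.45))
        animals.append(
            AnimalSpec(
                animal_id=animal_id,
                heart_rate=hr,
                ventricle=VentricleParams(
                    e_max=base.ventricle.e_max * jit(0.10),
                    e_min=base.ventricle.e_min * jit(0.10),
                    v0=base.ventricle.v0,
                    t_sys_frac=float(np.clip(base.ventricle.t_sys_frac * jit(0.04), 0.3, 0.55)),
                ),
                circulation=CirculationParams(
                    r_valve_ao=base.circulation.r_valve_ao,
                    r_char=base.circulation.r_char * jit(0.10),
                    r_periph=base.circulation.r_periph * jit(0.10),
                    c_art=base.circulation.c_art * jit(0.10),
                    p_ven=base.circulation.p_ven * jit(0.08),
                    r_mitral=base.circulation.r_mitral,
                ),
                alpha_true=alpha,
                volume_offset=float(rng.normal(8.0, 4.0)),
            )
        )
    return animals


def normalized_elastance(t_norm, params: VentricleParams):
    """Activation a(t) in [0, 1] at cycle phase ``t_norm`` in [0, 1).

    Double-cosine: rises 0 -> 1 over [0, peak], falls 1 -> 0 over
    [peak, t_sys_frac], zero in diastole.  Instantaneous elastance is
    ``E(t) = e_min + (e_max - e_min) a(t)``.  Vectorized over ``t_norm``.
    """
    t = np.asarray(t_norm, dtype=float)
    if np.any(t < 0) or np.any(t >= 1):
        raise ValueError("t_norm must lie in [0, 1)")
    t_sys = params.t_sys_frac
    t_peak = t_sys * _PEAK_FRAC
    rise = 0.5 * (1.0 - np.cos(np.pi * t / t_peak))
    fall = 0.5 * (1.0 + np.cos(np.pi * (t - t_peak) / (t_sys - t_peak)))
    a = np.where(t < t_peak, rise, np.where(t < t_sys, fall, 0.0))
    return float(a) if np.isscalar(t_norm) else a


def _activation_scalar(phase: float, t_sys: float, t_peak: float) -> float:
    # scalar fast path used inside the RK4 loop
    if phase < t_peak:
        return 0.5 * (1.0 - math.cos(math.pi * phase / t_peak))
    if phase < t_sys:
        return 0.5 * (1.0 + math.cos(math.pi * (phase - t_peak) / (t_sys - t_peak)))
    return 0.0


def apply_condition(base: AnimalSpec, cond: ConditionSpec) -> AnimalSpec:
    """Return a copy of ``base`` with the condition's multipliers applied.

    Multiplier keys name fields of the animal, its ventricle, or its
    circulation (e.g. ``e_max``, ``p_ven``, ``heart_rate``).
    """
    vent = dataclasses.asdict(base.ventricle)
    circ = dataclasses.asdict(base.circulation)
    hr = base.heart_rate
    for key, factor in cond.multipliers.items():
        if key == "heart_rate":
            hr *= factor
        elif key in vent:
            vent[key] *= factor
        elif key in circ:
            circ[key] *= factor
        else:
            raise ConfigError(f"condition {cond.name!r} targets unknown parameter {key!r}")
    return dataclasses.replace(
        base,
        heart_rate=hr,
        ventricle=VentricleParams(**vent),
        circulation=CirculationParams(**circ),
    )


def simulate_record(
    animal: AnimalSpec,
    cond: ConditionSpec | None,
    cfg: SimConfig,
    full_output: bool = False,
):
    """Integrate the model and return the noise-free ("true") record.

    The condition (if given) is applied to the animal first.  ``>=
    cfg.warmup_cycles`` cycles are integrated and discarded before
    recording, so the returned cycles are periodic steady state.  The ECG
    channel is an impulse train with one unit spike at each cycle onset.

    With ``full_output=True`` also returns a dict of internal signals
    (q_mit, q_regurg, arterial pressure, activation) for diagnostics.
    """
    eff = apply_condition(animal, cond) if cond is not None else animal
    vent, circ = eff.ventricle, eff.circulation

    fs = cfg.fs
    dt = 1.0 / fs
    period = 60.0 / eff.heart_rate
    spc = fs * period  # samples per cycle (float)
    n_rec = int(round(cfg.n_cycles * spc))
    n_warm = int(round(cfg.warmup_cycles * spc))
    n_total = n_warm + n_rec

    e_max, e_min, v0 = vent.e_max, vent.e_min, vent.v0
    t_sys, t_peak = vent.t_sys_frac, vent.t_sys_frac * _PEAK_FRAC
    r_fwd = circ.r_valve_ao + circ.r_char
    r_char, r_valve = circ.r_char, circ.r_valve_ao
    r_periph, c_art = circ.r_periph, circ.c_art
    p_ven, r_mitral = circ.p_ven, circ.r_mitral
    regurg = circ.regurg_frac
    de = e_max - e_min

    # steady-ish initial state: full ventricle, typical arterial pressure
    v_lv = v0 + p_ven / e_min
    p_art = 70.0

    p_ao_out = np.empty(n_total)
    q_ao_out = np.empty(n_total)
    p_lv_out = np.empty(n_total)
    v_lv_out = np.empty(n_total)

    inv_period = 1.0 / period
    act = _activation_scalar

    def deriv(v, pa, phase):
        e = e_min + de * act(phase, t_sys, t_peak)
        p_lv = e * (v - v0)
        q_ao = (p_lv - pa) / r_fwd if p_lv > pa else 0.0
        q_mit = (p_ven - p_lv) / r_mitral if p_ven > p_lv else 0.0
        q_reg = regurg * (p_lv - p_ven) / r_mitral if (regurg > 0.0 and p_lv > p_ven) else 0.0
        dv = q_mit - q_ao - q_reg
        dpa = (q_ao - (pa - P_VEN_REF) / r_periph) / c_art
        return dv, dpa

    if full_output:
        q_mit_out = np.empty(n_total)
        q_reg_out = np.empty(n_total)
        p_art_out = np.empty(n_total)
        act_out = np.empty(n_total)

    for i in range(n_total):
        t = i * dt
        phase = (t * inv_period) % 1.0
        e = e_min + de * act(phase, t_sys, t_peak)
        p_lv = e * (v_lv - v0)
        q_ao = (p_lv - p_art) / r_fwd if p_lv > p_art else 0.0
        p_ao = p_art + q_ao * r_char
        p_lv_out[i] = p_lv
        v_lv_out[i] = v_lv
        q_ao_out[i] = q_ao
        p_ao_out[i] = p_ao
        if full_output:
            q_mit_out[i] = (p_ven - p_lv) / r_mitral if p_ven > p_lv else 0.0
            q_reg_out[i] = (
                regurg * (p_lv - p_ven) / r_mitral if (regurg > 0.0 and p_lv > p_ven) else 0.0
            )
            p_art_out[i] = p_art
            act_out[i] = act(phase, t_sys, t_peak)

        # classic RK4 step
        ph_mid = ((t + 0.5 * dt) * inv_period) % 1.0
        ph_end = ((t + dt) * inv_period) % 1.0
        k1v, k1p = deriv(v_lv, p_art, phase)
        k2v, k2p = deriv(v_lv + 0.5 * dt * k1v, p_art + 0.5 * dt * k1p, ph_mid)
        k3v, k3p = deriv(v_lv + 0.5 * dt * k2v, p_art + 0.5 * dt * k2p, ph_mid)
        k4v, k4p = deriv(v_lv + dt * k3v, p_art + dt * k3p, ph_end)
        v_lv += dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
        p_art += dt * (k1p + 2.0 * k2p + 2.0 * k3p + k4p) / 6.0

        if not (math.isfinite(v_lv) and math.isfinite(p_art)):
            raise SimulationError(
                f"integration diverged at t={t:.3f}s for animal {eff.animal_id!r}"
            )
        if v_lv <= 0.0:
            raise SimulationError(
                f"negative LV volume at t={t:.3f}s; check e_min/p_ven/r_mitral "
                f"for animal {eff.animal_id!r}"
            )

    # cycle onsets that fall inside the recorded window
    onsets = [
        int(round(k * spc)) - n_warm
        for k in range(cfg.warmup_cycles, cfg.warmup_cycles + cfg.n_cycles)
    ]
    onsets = [s for s in onsets if 0 <= s < n_rec]
    ecg = np.zeros(n_rec)
    ecg[onsets] = 1.0

    meta = {
        "animal_id": eff.animal_id,
        "condition": cond.name if cond is not None else "baseline",
        "measurement_index": 0,
        "seed": cfg.seed,
        "heart_rate": eff.heart_rate,
        "r_onset_samples": onsets,
    }
    record = WaveformRecord(
        fs=fs,
        ecg=ecg,
        p_ao=p_ao_out[n_warm:],
        q_ao=q_ao_out[n_warm:] * 0.06,  # mL/s -> L/min
        p_lv=p_lv_out[n_warm:],
        v_lv=v_lv_out[n_warm:],
        meta=meta,
    )
    if not full_output:
        return record
    internals = {
        "q_mit_mls": q_mit_out[n_warm:],
        "q_regurg_mls": q_reg_out[n_warm:],
        "q_ao_mls": q_ao_out[n_warm:],
        "p_art_mmHg": p_art_out[n_warm:],
        "activation": act_out[n_warm:],
    }
    return record, internals


def measurement_model(true_record: WaveformRecord, animal: AnimalSpec, cfg: SimConfig) -> WaveformRecord:
    """Apply the measurement chain to a true record.

    The conductance-catheter volume is scaled by ``alpha_true`` and
    shifted by ``volume_offset``; every channel then receives additive
    Gaussian noise at the configured SD.  Seeded and reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    n = true_record.n_samples

    def noisy(x, sd):
        return x + rng.normal(0.0, sd, size=n) if sd > 0 else x.copy()

    v_meas = animal.alpha_true * true_record.v_lv + animal.volume_offset
    return true_record.replace(
        ecg=noisy(true_record.ecg, cfg.noise_ecg),
        p_ao=noisy(true_record.p_ao, cfg.noise_p_ao),
        q_ao=noisy(true_record.q_ao, cfg.noise_q_ao),
        p_lv=noisy(true_record.p_lv, cfg.noise_p_lv),
        v_lv=noisy(v_meas, cfg.noise_v_lv),
        meta=dict(true_record.meta),
    )


def mean_flow_lpm(record: WaveformRecord) -> float:
    """Mean aortic flow over the whole record (L/min); a CO estimate."""
    return float(np.mean(record.q_ao))


def conditions_default() -> dict[str, ConditionSpec]:
    """All six default conditions keyed by name."""
    return {name: ConditionSpec.default(name) for name in CONDITION_NAMES}
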