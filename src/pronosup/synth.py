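"""Synthetic MARG recordings of the seven-phase pronation-supination task.

The generator builds ground-truth kinematics first and derives ideal sensor
signals from them, so every recording carries its own reference:

1. a forearm roll profile for the PS phase — alternating cosine-eased hand
   turns between a supination target (~+120° from the palm-vertical hold
   posture) and a pronation target (~−30°), with per-turn amplitude/rate
   decrement, lognormal rhythm jitter and inserted pauses (interruptions);
2. a pitch profile that ramps 0 → ~45° during the lift and back during the
   lowering phase;
3. ground-truth quaternions from (roll, pitch), then ideal body-frame
   angular rate via quaternion differentiation (ω = 2 q* ⊗ q̇), ideal
   accelerometer (rotated gravity) and magnetometer (rotated reference
   field) signals;
4. additive i.i.d. Gaussian noise per channel.

Severity classes 0-4 map onto the clinical rubric bands: interruption
counts 0 / 1–2 / 3–5 / >5, progressive slowing, and decrement onset moving
from the end of the sequence toward its start; class 4 barely performs the
task (amplitude and rate below 25% of normal, erratic rhythm).  The exact
numeric bands are generator conventions, not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .orientation import OrientationTrace
from .segmentation import PHASES, PhaseSegmentation
from .signal_io import (ACCEL_RANGE_G, GYRO_RANGE_DPS, MAG_RANGE_UT, ImuTrace,
                        Placement, Recording, write_imu_csv)

__all__ = ["SynthParams", "SynthRecording", "severity_to_params", "generate",
           "generate_dataset", "MAG_REFERENCE_UT"]

SAMPLE_RATE = 100.0

#: earth magnetic field reference (µT): x = magnetic north, z = up.
MAG_REFERENCE_UT = np.array([20.7, 0.0, -44.4])

DEFAULT_PHASE_DURATIONS = {
    "RE1": 2.0, "LI": 1.5, "HO1": 1.0, "HO2": 1.0, "LO": 1.5, "RE2": 2.0,
}


@dataclass
class SynthParams:
    """Kinematic and noise parameters of one synthetic task execution."""

    n_turns: int = 12
    peak_rate: float = 350.0          # °/s at full performance
    supination_peak: float = 120.0    # ° above the hold posture
    pronation_peak: float = 30.0      # ° below the hold posture
    decrement_coeff: float = 1.0      # per-turn amplitude/rate multiplier
    decrement_onset: float = 1.0      # fraction of the sequence where decay starts
    n_interruptions: int = 0
    interruption_dur: float = 0.7     # s, nominal pause length
    rhythm_jitter_sd: float = 0.03    # lognormal sd on turn durations
    lift_angle: float = 45.0          # °
    phase_durations: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS))
    noise_accel_g: float = 0.02
    noise_gyro_dps: float = 2.0
    noise_mag_ut: float = 5.0
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        if self.n_turns < 10:
            raise ParameterError("task requires at least 10 turns")
        if not (0.0 < self.decrement_coeff <= 1.0):
            raise ParameterError("decrement_coeff must be in (0, 1]")
        if not (0.0 <= self.decrement_onset <= 1.0):
            raise ParameterError("decrement_onset must be in [0, 1]")
        if self.n_interruptions < 0 or self.peak_rate <= 0:
            raise ParameterError("invalid synthesis parameters")
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")


@dataclass
class SynthRecording:
    """A generated recording with its ground truth."""

    recording: Recording
    truth_quat: OrientationTrace
    truth_phases: PhaseSegmentation
    truth_class: int
    params: SynthParams
    ideal_gyro: np.ndarray | None = None  # noiseless gyro, °/s

    @property
    def truth_gyro_x(self) -> np.ndarray:
        """Ideal (noiseless) forearm-axis angular rate, °/s."""
        return self.ideal_gyro[:, 0]


# ---------------------------------------------------------------------------
# severity model
# ---------------------------------------------------------------------------

#: class -> (speed factor band, amplitude factor, decrement coeff band,
#:           decrement onset, interruption count band, jitter sd,
#:           interruption duration s)
#: Interruptions lengthen with severity: mild disease hesitates briefly,
#: severe disease freezes for a second or more.
_SEVERITY_BANDS = {
    0: ((0.92, 1.08), 1.0, (1.00, 1.00), 1.0, (0, 0), 0.02, 0.0),
    1: ((0.78, 0.92), 1.0, (0.960, 0.985), 0.8, (1, 2), 0.06, 0.25),
    2: ((0.60, 0.76), 1.0, (0.930, 0.960), 0.5, (3, 5), 0.12, 0.45),
    3: ((0.42, 0.56), 1.0, (0.890, 0.930), 0.1, (6, 9), 0.24, 0.80),
    4: ((0.18, 0.25), 0.2, (0.950, 1.000), 0.0, (8, 12), 0.32, 1.00),
}


def severity_to_params(updrs_class: int, seed: int) -> SynthParams:
    """Draw task parameters inside the band of one UPDRS severity class.

    Class 0 performs at full speed with no interruptions or decrement;
    classes 1-3 follow the rubric's interruption counts (1-2 / 3-5 / >5)
    with decrement starting near the end, midway, and right after the first
    turns; class 4 barely performs the task.  Deterministic given
    (class, seed).
    """
    if updrs_class not in _SEVERITY_BANDS:
        raise ParameterError(f"UPDRS class must be 0..4, got {updrs_class}")
    rng = np.random.default_rng(seed)
    (speed_band, amp, dec_band, onset, inter_band, jitter,
     inter_dur) = _SEVERITY_BANDS[updrs_class]
    speed = rng.uniform(*speed_band)
    dec = rng.uniform(*dec_band)
    n_inter = int(rng.integers(inter_band[0], inter_band[1] + 1))
    return SynthParams(
        n_turns=12,
        peak_rate=350.0 * speed,
        supination_peak=120.0 * amp * rng.uniform(0.95, 1.05),
        pronation_peak=30.0 * amp * rng.uniform(0.9, 1.1),
        decrement_coeff=dec,
        decrement_onset=onset,
        n_interruptions=n_inter,
        interruption_dur=inter_dur,
        rhythm_jitter_sd=jitter,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _ps_schedule(params: SynthParams, rng) -> list[tuple[str, float, float, float]]:
    """PS-phase event list: ("turn"|"hold", duration, roll_from, roll_to)."""
    n = params.n_turns
    onset_turn = int(np.floor(params.decrement_onset * n))
    env = np.array([params.decrement_coeff ** max(0, k - onset_turn + 1)
                    if k >= onset_turn else 1.0 for k in range(n)])
    sign = 1.0 if params.side == "right" else -1.0
    targets = [sign * (params.supination_peak * env[k] if k % 2 == 0
                       else -params.pronation_peak * env[k])
               for k in range(n)]
    # pauses at randomly chosen interior turn boundaries
    n_pause = min(params.n_interruptions, n - 1)
    pause_at = set(rng.choice(np.arange(1, n), size=n_pause, replace=False).tolist()) \
        if n_pause else set()

    events = []
    cur = 0.0
    for k in range(n):
        if k in pause_at:
            dur = params.interruption_dur * rng.uniform(0.5, 1.5)
            events.append(("hold", dur, cur, cur))
        tgt = targets[k]
        delta = abs(tgt - cur)
        rate = params.peak_rate * env[k]
        T = delta * np.pi / (2.0 * rate)
        T *= float(np.exp(rng.normal(0.0, params.rhythm_jitter_sd)))
        T = max(T, 0.05)
        events.append(("turn", T, cur, tgt))
        cur = tgt
    return events


def _ease(s: np.ndarray) -> np.ndarray:
    """Cosine easing 0→1 with zero end-point slopes."""
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _euler_to_quat(roll_deg: np.ndarray, pitch_deg: np.ndarray) -> np.ndarray:
    """Vectorized sensor-to-earth quaternions for yaw = 0."""
    p = np.radians(pitch_deg) / 2.0
    r = np.radians(roll_deg) / 2.0
    cp, sp, cr, sr = np.cos(p), np.sin(p), np.cos(r), np.sin(r)
    return np.column_stack([cp * cr, cp * sr, -sp * cr, sp * sr])


def _body_rates(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Body-frame angular rate ω = 2 q* ⊗ q̇ from finite differences, rad/s."""
    qd = np.gradient(q, t, axis=0)
    w, x, y, z = q.T
    wd, xd, yd, zd = qd.T
    wx = w * xd - x * wd - y * zd + z * yd
    wy = w * yd + x * zd - y * wd - z * xd
    wz = w * zd - x * yd + y * xd - z * wd
    return 2.0 * np.column_stack([wx, wy, wz])


def _sensor_vectors(q: np.ndarray, v_earth: np.ndarray) -> np.ndarray:
    """Rotate an earth-frame vector into the sensor frame for every sample."""
    w, x, y, z = q.T
    row1 = np.column_stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                            2 * (x * z + w * y)])
    row2 = np.column_stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                            2 * (y * z - w * x)])
    row3 = np.column_stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                            1 - 2 * (x * x + y * y)])
    return v_earth[0] * row1 + v_earth[1] * row2 + v_earth[2] * row3


def _trace_from_kinematics(t, q, rng, placement, params) -> tuple[ImuTrace, np.ndarray]:
    """Ideal 9-axis signals from a quaternion trajectory, plus noise."""
    gyro = np.degrees(_body_rates(q, t))
    accel = _sensor_vectors(q, np.array([0.0, 0.0, 1.0]))
    mag = _sensor_vectors(q, MAG_REFERENCE_UT)
    for name, arr, bound in (("gyro", gyro, GYRO_RANGE_DPS),
                             ("accel", accel, ACCEL_RANGE_G),
                             ("mag", mag, MAG_RANGE_UT)):
        if np.max(np.abs(arr)) > bound:
            raise GenerationError(
                f"ideal {name} signal exceeds the ±{bound:g} sensor range")
    noisy = ImuTrace(
        t=t,
        accel=np.clip(accel + rng.normal(0, params.noise_accel_g, accel.shape),
                      -ACCEL_RANGE_G, ACCEL_RANGE_G),
        gyro=np.clip(gyro + rng.normal(0, params.noise_gyro_dps, gyro.shape),
                     -GYRO_RANGE_DPS, GYRO_RANGE_DPS),
        mag=np.clip(mag + rng.normal(0, params.noise_mag_ut, mag.shape),
                    -MAG_RANGE_UT, MAG_RANGE_UT),
        placement=placement,
        sample_rate_nominal=SAMPLE_RATE,
    )
    return noisy, gyro


def generate(params: SynthParams, updrs_class: int = 0) -> SynthRecording:
    """Generate one labeled recording (wrist + upper-arm traces) with truth."""
    rng = np.random.default_rng(params.seed)
    events = _ps_schedule(params, rng)
    ps_dur = sum(e[1] for e in events)
    pd_ = params.phase_durations
    durs = [pd_["RE1"], pd_["LI"], pd_["HO1"], ps_dur,
            pd_["HO2"], pd_["LO"], pd_["RE2"]]
    edges = np.concatenate([[0.0], np.cumsum(durs)])
    total = edges[-1]
    dt = 1.0 / SAMPLE_RATE
    n = int(np.floor(total / dt)) + 1
    t = np.arange(n) * dt

    # pitch profile: 0 -> lift during LI, back during LO
    pitch = np.zeros(n)
    li_s, li_e = edges[1], edges[2]
    lo_s, lo_e = edges[5], edges[6]
    mask = (t >= li_s) & (t < li_e)
    pitch[mask] = params.lift_angle * _ease((t[mask] - li_s) / (li_e - li_s))
    pitch[(t >= li_e) & (t < lo_s)] = params.lift_angle
    mask = (t >= lo_s) & (t < lo_e)
    pitch[mask] = params.lift_angle * (1.0 - _ease((t[mask] - lo_s) / (lo_e - lo_s)))

    # roll profile: PS events, then hold at the final posture until rest
    roll = np.zeros(n)
    t_cursor = edges[3]
    final_roll = 0.0
    for kind, dur, r_from, r_to in events:
        mask = (t >= t_cursor) & (t < t_cursor + dur)
        if kind == "turn" and dur > 0:
            s = (t[mask] - t_cursor) / dur
            roll[mask] = r_from + (r_to - r_from) * _ease(s)
        else:
            roll[mask] = r_from
        t_cursor += dur
        final_roll = r_to
    roll[t >= t_cursor] = final_roll

    q = _euler_to_quat(roll, pitch)

    side = params.side
    wrist_pl = Placement.WRIST_RIGHT if side == "right" else Placement.WRIST_LEFT
    upper_pl = (Placement.UPPER_ARM_RIGHT if side == "right"
                else Placement.UPPER_ARM_LEFT)
    wrist_trace, ideal_gyro = _trace_from_kinematics(t, q, rng, wrist_pl, params)

    # upper arm: partial lift, no roll, small smooth sway
    from scipy.ndimage import uniform_filter1d
    sway = uniform_filter1d(rng.normal(0, 1.0, n), size=int(SAMPLE_RATE),
                            mode="nearest")
    sway *= 0.8 / max(np.max(np.abs(sway)), 1e-9)
    q_up = _euler_to_quat(sway, 0.35 * pitch)
    upper_trace, _ = _trace_from_kinematics(t, q_up, rng, upper_pl, params)

    idx = [int(np.searchsorted(t, b)) for b in edges[1:-1]] + [n]
    bounds = [0] + idx
    intervals = {label: (bounds[i], bounds[i + 1]) for i, label in enumerate(PHASES)}
    truth_phases = PhaseSegmentation(intervals=intervals, n_samples=n)

    rec = Recording(traces={wrist_pl: wrist_trace, upper_pl: upper_trace},
                    subject_id=f"synth-{params.seed}", side_performed=side)
    sr = SynthRecording(
        recording=rec,
        truth_quat=OrientationTrace(t=t, q=q, source_placement=wrist_pl),
        truth_phases=truth_phases,
        truth_class=int(updrs_class),
        params=params,
        ideal_gyro=ideal_gyro,
    )
    return sr


def generate_dataset(classes, per_class: int, seed: int,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[SynthRecording], pd.DataFrame]:
    """A reproducible labeled corpus: ``per_class`` recordings per class.

    When ``out_dir`` is given, writes raw wrist/upper-arm CSVs, truth-phase
    JSONs and a labels CSV.  Identical arguments yield identical outputs.
    """
    if per_class < 1:
        raise ParameterError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    recordings = []
    rows = []
    for cls in classes:
        for r in range(per_class):
            child_seed = int(rng.integers(0, 2**31 - 1))
            params = severity_to_params(cls, child_seed)
            rec = generate(params, updrs_class=cls)
            rec_id = f"c{cls}_r{r:03d}"
            recordings.append(rec)
            rows.append({"recording_id": rec_id, "label": int(cls),
                         "seed": child_seed})
    labels = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (rec_id, rec) in zip(labels["recording_id"], recordings):
            for pl, tr in rec.recording.traces.items():
                write_imu_csv(tr, out_dir / f"{rec_id}_{pl.value}.csv")
            rec.truth_phases.to_json(out_dir / f"{rec_id}_truth_phases.json",
                                     t=rec.truth_quat.t)
        labels.to_csv(out_dir / "labels.csv", index=False)
    return recordings, labels
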