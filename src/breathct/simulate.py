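"""Synthetic multi-device breath-measurement generator.

Emulates a pilot study in which the same subjects exhale into several
electronic-nose instruments back to back: 15 subjects, 3 visits, one breath
sample before (no-meal) and one after (meal) a standardized test meal, on 3
devices. Every breath is a shared *latent* sample observed once per device
through a device-specific affine distortion, which is exactly the
standard-sample linkage the calibration-transfer methods rely on.

Latent model (additive Gaussian):

    x = baseline + class_effect * [meal] + subject + visit + noise

Subject and visit effects are *structured*: they live along a small set of
shared nuisance directions (sensor-array responses are highly collinear and
person-to-person variation dominates a few axes), while the measurement noise
is isotropic. This anisotropy matters: it is what makes a master-trained
classifier degrade on a distorted device, because the master's discriminant
suppresses the high-variance nuisance axes and a device rotation mixes them
back into the decision direction.

Observation model per device d:

    row = A_d x + b_d + device noise

Defaults place device 1 (the master) at the identity and distort devices 2
and 3 with ``A_d = I + eps * Q_d`` (Q_d a random orthogonal matrix) plus an
offset, calibrated so that a classifier trained on the master degrades on the
slaves (within-device AUC ~0.9, cross-device ~0.75) while remaining
recoverable by an affine transfer mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    ALL_COLUMNS,
    FEATURE_COLUMNS,
    N_SENSORS,
    RawMeasurement,
    TIMEPOINT_TO_CLASS,
)

# Fixed construction seed for the *default* device distortions and class
# pattern: the defaults are part of the study definition, not of a particular
# run, so they must not move with the user-facing seed.
_DEFAULTS_SEED = 202115

# Default distortion/effect scales (frozen study conditions; see docs/methods.md)
_DEVICE_EPS = 0.60          # rotation admixture in A_d = I + eps Q_d
_DEVICE_OFFSET_SD = 0.35    # per-feature sd of the device offset (~1 latent sd)
_CLASS_EFFECT_NORM = 0.55   # Euclidean norm of the meal-vs-no-meal latent shift
_NUISANCE_RANK = 5          # shared subject/visit variation directions
_NUISANCE_TAPER = np.linspace(1.8, 0.8, _NUISANCE_RANK)  # per-direction sd multipliers
_BASELINE_LOW, _BASELINE_HIGH = 1.6, 3.0


def _default_baseline(k: int) -> np.ndarray:
    return np.linspace(_BASELINE_LOW, _BASELINE_HIGH, k)


def _default_class_effect(k: int) -> np.ndarray:
    rng = np.random.default_rng(_DEFAULTS_SEED)
    v = rng.normal(size=k)
    return _CLASS_EFFECT_NORM * v / np.linalg.norm(v)


def _nuisance_basis(k: int) -> np.ndarray:
    """Fixed orthonormal k x r basis of the shared nuisance directions."""
    rng = np.random.default_rng(_DEFAULTS_SEED + 2)
    r = min(_NUISANCE_RANK, k)
    q, _ = np.linalg.qr(rng.normal(size=(k, r)))
    return q[:, :r]


def _random_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(k, k)))
    return q * np.sign(np.diag(r))


def _default_devices(
    k: int, n_devices: int, baseline: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Device gains/offsets: master = identity, slaves distorted.

    Slave gain ``A = I + eps Q`` acts around the latent baseline (the offset
    absorbs ``(I - A) baseline``) so that feature levels stay positive, plus a
    small random shift of ~1 latent sd per feature.
    """
    rng = np.random.default_rng(_DEFAULTS_SEED + 1)
    gains = [np.eye(k)]
    offsets = [np.zeros(k)]
    for _ in range(1, n_devices):
        A = np.eye(k) + _DEVICE_EPS * _random_orthogonal(k, rng)
        delta = rng.normal(scale=_DEVICE_OFFSET_SD, size=k)
        b = baseline - A @ baseline + delta
        gains.append(A)
        offsets.append(b)
    return gains, offsets


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    ``drop_counts = (n_meal, n_no_meal)`` removes that many latent samples per
    class (a failed exhalation disappears on *all* devices), reproducing the
    86-sample, 41 meal / 45 no-meal composition by default. Set it to None and
    use ``missing_fraction`` for random dropout instead.
    """

    n_devices: int = 3
    n_subjects: int = 15
    n_visits: int = 3
    n_sensors: int = N_SENSORS
    class_effect: np.ndarray | None = None
    subject_sd: float = 0.60
    visit_sd: float = 0.30
    noise_sd: float = 0.18
    device_gain: list | None = None
    device_offset: list | None = None
    standard_noise_sd: float = 0.05
    missing_fraction: float = 0.0
    drop_counts: tuple | None = (4, 0)
    seed: int = 0

    baseline: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_sensors < 2:
            raise ValueError("need at least 2 sensors")
        if min(self.n_devices, self.n_subjects, self.n_visits) < 1:
            raise ValueError("counts must be positive")
        for name in ("subject_sd", "visit_sd", "noise_sd", "standard_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        k = self.n_sensors
        self.baseline = _default_baseline(k)
        if self.class_effect is None:
            self.class_effect = _default_class_effect(k)
        else:
            self.class_effect = np.asarray(self.class_effect, dtype=float)
            if self.class_effect.shape != (k,):
                raise ValueError(f"class_effect must have shape ({k},)")
        if self.device_gain is None or self.device_offset is None:
            gains, offsets = _default_devices(k, self.n_devices, self.baseline)
            if self.device_gain is None:
                self.device_gain = gains
            if self.device_offset is None:
                self.device_offset = offsets
        self.device_gain = [np.asarray(a, dtype=float) for a in self.device_gain]
        self.device_offset = [np.asarray(b, dtype=float) for b in self.device_offset]
        if len(self.device_gain) != self.n_devices or len(self.device_offset) != self.n_devices:
            raise ValueError("need one gain matrix and offset per device")
        for d, A in enumerate(self.device_gain):
            if A.shape != (k, k):
                raise ValueError(f"device_gain[{d}] must be {k}x{k}")
            if not np.isfinite(np.linalg.cond(A)) or np.linalg.cond(A) > 1e12:
                raise ValueError(f"device_gain[{d}] is not invertible")


@dataclass
class LatentSample:
    """One breath event, shared by all devices (the standard-sample link)."""

    sample_id: str
    subject_id: int
    visit: int
    timepoint: str  # "pre" (no-meal) | "post" (meal)
    latent_vector: np.ndarray


def make_latent(config: SimConfig, rng: np.random.Generator) -> list[LatentSample]:
    """Draw the latent breath samples of one study.

    Produces ``n_subjects * n_visits * 2`` samples minus the configured drops;
    subject and visit effects are shared within their grouping, the class
    effect shifts every post-meal sample by the same vector.
    """
    k = config.n_sensors
    U = _nuisance_basis(k)
    taper = _NUISANCE_TAPER[: U.shape[1]]
    samples: list[LatentSample] = []
    for s in range(1, config.n_subjects + 1):
        subj_eff = U @ (rng.normal(size=U.shape[1]) * config.subject_sd * taper)
        for v in range(1, config.n_visits + 1):
            visit_eff = U @ (rng.normal(size=U.shape[1]) * config.visit_sd * taper)
            for tp in ("pre", "post"):
                x = config.baseline + subj_eff + visit_eff
                if tp == "post":
                    x = x + config.class_effect
                x = x + rng.normal(scale=config.noise_sd, size=k)
                samples.append(
                    LatentSample(
                        sample_id=f"S{s:02d}_V{v}_{tp}",
                        subject_id=s,
                        visit=v,
                        timepoint=tp,
                        latent_vector=x,
                    )
                )
    if config.drop_counts is not None:
        n_drop = {"post": config.drop_counts[0], "pre": config.drop_counts[1]}
        dropped: set[str] = set()
        for tp, nd in n_drop.items():
            pool = [s.sample_id for s in samples if s.timepoint == tp]
            if nd > len(pool):
                raise ValueError(f"cannot drop {nd} of {len(pool)} {tp} samples")
            if nd:
                dropped.update(rng.choice(pool, size=nd, replace=False))
        samples = [s for s in samples if s.sample_id not in dropped]
    elif config.missing_fraction > 0:
        keep = rng.random(len(samples)) >= config.missing_fraction
        samples = [s for s, k_ in zip(samples, keep) if k_]
    return samples


def observe(
    latent: list[LatentSample],
    device_id: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observe the latent samples on one device: ``row = A_d x + b_d + noise``.

    ``device_id`` is 1-based (device 1 is the master). Rows carry the latent
    sample_id, so matched rows across devices are standard samples.
    """
    if not 1 <= device_id <= config.n_devices:
        raise ValueError(f"device_id must be in 1..{config.n_devices}")
    A = config.device_gain[device_id - 1]
    b = config.device_offset[device_id - 1]
    rows = []
    for s in latent:
        x = A @ s.latent_vector + b
        if config.standard_noise_sd > 0:
            x = x + rng.normal(scale=config.standard_noise_sd, size=config.n_sensors)
        rows.append(
            {
                "sample_id": s.sample_id,
                "device_id": device_id,
                "subject_id": s.subject_id,
                "visit": s.visit,
                "timepoint": s.timepoint,
                "class": TIMEPOINT_TO_CLASS[s.timepoint],
                **dict(zip(FEATURE_COLUMNS[: config.n_sensors], x)),
            }
        )
    cols = ALL_COLUMNS if config.n_sensors == N_SENSORS else (
        ALL_COLUMNS[:6] + FEATURE_COLUMNS[: config.n_sensors]
    )
    return pd.DataFrame(rows, columns=cols)


def simulate_study(config: SimConfig) -> dict[int, pd.DataFrame]:
    """Full study: one linked feature table per device, keyed by device id.

    All randomness derives from ``config.seed``; the same seed regenerates
    bit-identical tables.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_devices)
    latent = make_latent(config, np.random.default_rng(children[0]))
    return {
        d: observe(latent, d, config, np.random.default_rng(children[d]))
        for d in range(1, config.n_devices + 1)
    }


@dataclass
class TraceConfig:
    """Raw-trace synthesis parameters (times in seconds, resistance in ohm)."""

    sample_rate_hz: float = 4.0
    baseline_s: float = 10.0
    breath_s: float = 20.0
    cleaning_s: float = 3.0
    baseline_resistance_ohm: float = 1.0e5
    tau_s: float = 2.0       # exponential settling time of the breath response
    noise_rel: float = 0.0   # multiplicative noise sd relative to the level


def simulate_traces(
    row: pd.Series,
    trace_config: TraceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[RawMeasurement]:
    """Per-sensor resistance traces consistent with a feature-table row.

    Each sensor's trace holds the baseline resistance R0 for 10 s, then decays
    exponentially toward ``R = R0 / f`` during the 20 s breath phase (settled
    well before the final 5 s steady-state window), then a short cleaning
    phase. ``extract_feature`` recovers f up to the configured noise.
    """
    cfg = trace_config or TraceConfig()
    rng = rng or np.random.default_rng(0)
    feats = {c: float(row[c]) for c in FEATURE_COLUMNS if c in row.index}
    if any(f <= 0 for f in feats.values()):
        raise ValueError("features must be positive to synthesize traces")
    dt = 1.0 / cfg.sample_rate_hz
    t = np.arange(0.0, cfg.baseline_s + cfg.breath_s + cfg.cleaning_s, dt)
    phase = np.where(
        t < cfg.baseline_s,
        "baseline",
        np.where(t < cfg.baseline_s + cfg.breath_s, "breath", "cleaning"),
    ).astype(object)
    traces = []
    for sensor, f in feats.items():
        r0 = cfg.baseline_resistance_ohm
        r_level = r0 / f
        r = np.full_like(t, r0)
        breath = phase == "breath"
        tb = t[breath] - cfg.baseline_s
        r[breath] = r_level + (r0 - r_level) * np.exp(-tb / cfg.tau_s)
        r[phase == "cleaning"] = r0
        if cfg.noise_rel > 0:
            r = r * (1.0 + rng.normal(scale=cfg.noise_rel, size=r.shape))
        traces.append(
            RawMeasurement(
                sample_id=str(row["sample_id"]),
                sensor_id=sensor,
                t_seconds=t.copy(),
                resistance_ohm=r,
                phase=phase.copy(),
            )
        )
    return traces


def traces_to_frame(traces: list[RawMeasurement]) -> pd.DataFrame:
    """Long-format trace table (sample_id, sensor, t_seconds, resistance_ohm, phase)."""
    parts = [
        pd.DataFrame(
            {
                "sample_id": tr.sample_id,
                "sensor": tr.sensor_id,
                "t_seconds": tr.t_seconds,
                "resistance_ohm": tr.resistance_ohm,
                "phase": tr.phase,
            }
        )
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> list[RawMeasurement]:
    traces = []
    for (sid, sensor), g in frame.groupby(["sample_id", "sensor"], sort=True):
        g = g.sort_values("t_seconds")
        traces.append(
            RawMeasurement(
                sample_id=str(sid),
                sensor_id=str(sensor),
                t_seconds=g["t_seconds"].to_numpy(float),
                resistance_ohm=g["resistance_ohm"].to_numpy(float),
                phase=g["phase"].to_numpy(object),
            )
        )
    return traces
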