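"""Synthetic ERP epoch generator.

Emulates averaged Pz "probe" responses from a concealed-information (guilty
knowledge) protocol: a guilty group whose probe responses carry a P300 — a
positive deflection peaking ~300–400 ms after the stimulus — and an innocent
group whose probe responses are background EEG only.  Real recordings of this
kind are 0.1–30 Hz band-passed scalp potentials digitized at 500 Hz, epoched
from 0.2 s before to 0.8 s after stimulus onset; the generator reproduces that
geometry so every downstream stage (preprocessing, feature extraction,
selection, classification) can be exercised end to end.

The P300 is modelled as a raised-cosine (Hann) bump: smooth, compactly
supported and monophasic, which is what an averaged P3 at Pz looks like.
Between-subject amplitude variation, trial-level amplitude and latency jitter
and additive noise (white, or AR(1) to mimic the 1/f-ish EEG background) are
all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = ["SimConfig", "ErpResponse", "generate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic ERP study.

    Defaults mirror the emulated study: 14 subjects per class, epochs from
    −0.2 s to +0.8 s at 500 Hz (500 samples), P3 latency 0.35 ± 0.03 s, and
    enough trials that 5-trial averaging leaves ~21 averaged responses per
    subject (~294 per class, i.e. "approximately 300" per group).
    """

    n_subjects_per_class: int = 14
    trials_per_subject: int = 105
    avg_group_size: int = 5
    fs: float = 500.0
    epoch_start: float = -0.2
    epoch_end: float = 0.8
    p3_amplitude_mean: float = 10.0  # µV, typical averaged P300 at Pz
    p3_amplitude_sd: float = 1.0  # µV, trial-level variation
    p3_latency_mean: float = 0.35  # s
    p3_latency_sd: float = 0.03  # s, trial-level jitter
    p3_width: float = 0.3  # s, full width of the raised-cosine bump
    noise_sd: float = 5.0  # µV, single-trial background amplitude
    noise_model: str = "white"  # "white" or "ar1"
    ar1_coeff: float = 0.95
    subject_amplitude_sd: float = 2.0  # µV, between-subject offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1 or self.trials_per_subject < 1:
            raise ValueError("subject and trial counts must be positive")
        if self.avg_group_size < 1:
            raise ValueError("avg_group_size must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.epoch_end <= self.epoch_start:
            raise ValueError("epoch_end must exceed epoch_start")
        for name in (
            "p3_amplitude_sd",
            "p3_latency_sd",
            "noise_sd",
            "subject_amplitude_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p3_width <= 0:
            raise ValueError("p3_width must be positive")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def n_samples(self) -> int:
        """Epoch length in samples (500 at the defaults)."""
        return int(round((self.epoch_end - self.epoch_start) * self.fs))

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ErpResponse:
    """One fixed-length sampled waveform.

    Sample ``i`` sits at time ``t0 + i / fs`` relative to stimulus onset
    (sample-start convention, half-open epoch), so a 1 s epoch at 500 Hz is
    exactly 500 samples.  ``label`` is +1 for P3 (guilty probe) and −1 for
    non-P3 (innocent probe).
    """

    samples: np.ndarray
    t0: float
    fs: float
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def _hann_bump(t: np.ndarray, amplitude: float, latency: float, width: float) -> np.ndarray:
    """Raised-cosine positivity: peak ``amplitude`` at ``latency``, support ``width``."""
    u = (t - latency) / width
    bump = np.where(np.abs(u) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * u)), 0.0)
    return amplitude * bump


def _noise(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(n)
    if cfg.noise_model == "white":
        return rng.normal(0.0, cfg.noise_sd, n)
    # AR(1) with stationary marginal sd = noise_sd
    phi = cfg.ar1_coeff
    innov_sd = cfg.noise_sd * np.sqrt(max(1.0 - phi * phi, 0.0))
    e = rng.normal(0.0, innov_sd, n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, cfg.noise_sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def generate_dataset(config: SimConfig) -> list[ErpResponse]:
    """Generate single-trial epochs for both groups.

    Subjects ``G01..`` carry the P3 (label +1); subjects ``I01..`` are
    noise-only (label −1).  Each P3 trial is a Hann bump whose amplitude is
    ``p3_amplitude_mean`` + a per-subject offset + trial-level variation, and
    whose latency jitters around ``p3_latency_mean``.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    t = config.epoch_start + np.arange(config.n_samples) / config.fs
    width = max(int(np.ceil(np.log10(config.n_subjects_per_class + 1))), 2)
    out: list[ErpResponse] = []
    for label, prefix in ((1, "G"), (-1, "I")):
        for s in range(config.n_subjects_per_class):
            sid = f"{prefix}{s + 1:0{width}d}"
            subj_offset = rng.normal(0.0, config.subject_amplitude_sd) if config.subject_amplitude_sd else 0.0
            for _ in range(config.trials_per_subject):
                x = _noise(rng, config.n_samples, config)
                if label == 1:
                    amp = config.p3_amplitude_mean + subj_offset
                    if config.p3_amplitude_sd:
                        amp += rng.normal(0.0, config.p3_amplitude_sd)
                    lat = config.p3_latency_mean
                    if config.p3_latency_sd:
                        lat += rng.normal(0.0, config.p3_latency_sd)
                    x = x + _hann_bump(t, amp, lat, config.p3_width)
                out.append(
                    ErpResponse(x, config.epoch_start, config.fs, sid, label)
                )
    return out
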