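"""Synthetic cohort generators with known ground truth.

Three generators emulate the trial's data streams so the whole pipeline is
testable without patient data:

* :func:`simulate_eeg` — NREM-II-like multichannel sleep EEG whose
  cross-channel second-order structure is planted through a coupling matrix;
* :func:`simulate_scales` — two-arm clinical-scale scores at five timepoints
  with configurable standardized effects;
* :func:`simulate_volumes` — paired regional gray-matter volume tables with
  configurable fractional regional changes.

EEG generative model
--------------------
Channels mix latent band-limited Gaussian sources.  Each channel ``i`` gets a
private source, each coupled pair ``(i, j)`` a shared source, and independent
band-limited sensor noise::

    x_i = sqrt(max(0, 1 - k_i)) * p_i + sum_j sqrt(c_ij) * s_ij + noise_sd * e_i

with ``k_i = sum_j c_ij``.  All sources have unit variance and identical
NREM-II-like spectra (delta-dominant plus a 12–14 Hz spindle band), so for an
isolated coupled pair the population Pearson correlation is analytically::

    rho_ij = c_ij / (1 + noise_sd**2)

which is monotone in the planted coupling — the property the downstream
Pearson-correlation networks are tested against.  Sensor noise is flat over
the 0.3–30 Hz analysis band (out-of-band noise power would be removed by the
band-pass anyway and would only obscure the spectral bookkeeping).  A
Gaussian source model is sufficient because the pipeline consumes only
second-order structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    InvalidDesignError,
    InvalidModelError,
    InvalidRegionError,
)
from .preprocess import EEGRecording
from .reference import (
    AAL_REGIONS,
    EEG_CHANNELS,
    N_CONTROL,
    N_TREATMENT,
    N_VBM_SUBJECTS,
    SAMPLING_RATE,
    SCALE_BASELINES,
    SCALE_TIMEPOINTS,
    gm_volume_summary,
)

#: Default NREM-II-like band profile: (band in Hz, relative power).
#: Delta dominates, with a sleep-spindle (sigma) band at lower power.
DEFAULT_BAND_PROFILE = (
    ((0.5, 4.0), 0.55),   # delta
    ((4.0, 8.0), 0.20),   # theta
    ((8.0, 12.0), 0.10),  # alpha
    ((12.0, 14.0), 0.10), # sigma / sleep spindles
    ((14.0, 30.0), 0.05), # beta
)

#: Spectral support of every latent source and of the sensor noise (Hz).
SOURCE_BAND = (0.3, 30.0)

#: Output amplitude scale: µV RMS of the unit-variance composite signal.
DEFAULT_AMPLITUDE_UV = 40.0


@dataclass
class CouplingModel:
    """Ground-truth generative model for multichannel NREM-II-like EEG.

    Parameters
    ----------
    coupling : ndarray, shape (n_channels, n_channels)
        Symmetric source-sharing weights in [0, 1] with zero diagonal.  For an
        isolated pair, the planted population correlation is
        ``c / (1 + noise_sd**2)``.
    noise_sd : float
        Independent sensor-noise SD in units of source SD (so ``noise_sd=1``
        gives per-channel SNR 1).
    band_profile : sequence of ((lo, hi), relative_power)
        Spectral content of the latent sources; bands must lie in [0.3, 30] Hz.
    """

    n_channels: int = 8
    coupling: np.ndarray | None = None
    noise_sd: float = 1.0
    band_profile: tuple = DEFAULT_BAND_PROFILE
    amplitude_uv: float = DEFAULT_AMPLITUDE_UV
    seed: int = 0

    def __post_init__(self):
        if self.coupling is None:
            self.coupling = np.zeros((self.n_channels, self.n_channels))
        self.coupling = np.asarray(self.coupling, dtype=float)
        c = self.coupling
        if c.shape != (self.n_channels, self.n_channels):
            raise InvalidModelError(
                f"coupling must be {self.n_channels}x{self.n_channels}, got {c.shape}"
            )
        if not np.allclose(c, c.T, atol=0.0):
            raise InvalidModelError("coupling matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise InvalidModelError("coupling diagonal must be zero")
        if np.any(c < 0) or np.any(c > 1):
            raise InvalidModelError("coupling entries must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidModelError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for (lo, hi), p in self.band_profile:
            if not (SOURCE_BAND[0] <= lo < hi <= SOURCE_BAND[1]):
                raise InvalidModelError(
                    f"band ({lo}, {hi}) Hz outside [{SOURCE_BAND[0]}, {SOURCE_BAND[1]}] Hz"
                )
            if p < 0:
                raise InvalidModelError("band powers must be >= 0")


def _band_filter_gain(n_samples: int, fs: float, bands) -> np.ndarray:
    """|H(f)| on the rfft grid for a flat-in-band spectrum, total power 1."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    psd = np.zeros_like(freqs)
    total = sum(p for _, p in bands)
    if total <= 0:
        raise InvalidModelError("band profile has no power")
    for (lo, hi), p in bands:
        mask = (freqs >= lo) & (freqs < hi)
        if mask.any():
            psd[mask] += (p / total) / mask.sum()
    return np.sqrt(psd)


def _band_limited_noise(rng, n_signals: int, n_samples: int, gain: np.ndarray) -> np.ndarray:
    """Unit-variance (in expectation) Gaussian signals with spectrum |gain|."""
    white = rng.standard_normal((n_signals, n_samples))
    spec = np.fft.rfft(white, axis=1) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    # exact variance of filtered unit white noise: sum of c_k |H_k|^2 / n,
    # c_k = 2 except at DC and (for even n) Nyquist
    c = np.full(gain.shape, 2.0)
    c[0] = 1.0
    if n_samples % 2 == 0:
        c[-1] = 1.0
    var = float(np.sum(c * gain**2) / n_samples)
    return x / np.sqrt(var)


def simulate_eeg(
    model: CouplingModel,
    duration: float = 160.0,
    fs: float = SAMPLING_RATE,
    subject_id: str = "",
    timepoint: str = "",
) -> EEGRecording:
    """Simulate a multichannel NREM-II-like EEG recording.

    Deterministic given ``model.seed``.  Channels are labelled with the
    canonical montage (C3, C4, P3, P4, O1, O2, P7, P8) when ``n_channels`` is
    8, otherwise ``ch01..chNN``.  Output is in µV.

    Raises
    ------
    InvalidArgumentError
        If ``duration`` or ``fs`` is non-positive.
    """
    if duration <= 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise InvalidArgumentError(f"fs must be positive, got {fs}")
    n = model.n_channels
    n_samples = int(round(duration * fs))
    rng = np.random.default_rng(model.seed)
    gain = _band_filter_gain(n_samples, fs, model.band_profile)

    kappa = model.coupling.sum(axis=1)
    private_w = np.sqrt(np.clip(1.0 - kappa, 0.0, None))

    x = private_w[:, None] * _band_limited_noise(rng, n, n_samples, gain)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if model.coupling[i, j] > 0]
    if pairs:
        shared = _band_limited_noise(rng, len(pairs), n_samples, gain)
        for k, (i, j) in enumerate(pairs):
            w = np.sqrt(model.coupling[i, j])
            x[i] += w * shared[k]
            x[j] += w * shared[k]
    if model.noise_sd > 0:
        noise_gain = _band_filter_gain(n_samples, fs, (((SOURCE_BAND), 1.0),))
        x += model.noise_sd * _band_limited_noise(rng, n, n_samples, noise_gain)

    labels = EEG_CHANNELS if n == len(EEG_CHANNELS) else tuple(f"ch{i + 1:02d}" for i in range(n))
    return EEGRecording(
        signal=model.amplitude_uv * x,
        fs=fs,
        channel_labels=labels,
        subject_id=subject_id,
        timepoint=timepoint,
    )


@dataclass
class TrialDesign:
    """Two-arm longitudinal scale-score design with planted effects.

    ``effect_sizes`` maps ``(measure, timepoint, arm)`` to a standardized mean
    shift in units of the total SD ``sqrt(between^2 + within^2)``.  Baseline
    is unshifted by construction in both arms.  Scores are drawn from a
    subject-level random-intercept model and truncated to each scale's valid
    range.
    """

    n_treatment: int = N_TREATMENT
    n_control: int = N_CONTROL
    timepoints: tuple = SCALE_TIMEPOINTS
    measures: tuple = tuple(SCALE_BASELINES)
    effect_sizes: dict = field(default_factory=dict)
    between_subject_sd: float = 15.0
    within_subject_sd: float = 5.0
    baselines: dict = field(default_factory=lambda: dict(SCALE_BASELINES))
    seed: int = 0

    def __post_init__(self):
        self.timepoints = tuple(self.timepoints)
        self.measures = tuple(self.measures)
        if self.n_treatment < 2 or self.n_control < 2:
            raise InvalidDesignError("need at least 2 subjects per arm")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise InvalidDesignError("timepoints must be unique")
        if self.between_subject_sd <= 0 or self.within_subject_sd <= 0:
            raise InvalidDesignError("SDs must be positive")
        for m in self.measures:
            if m not in self.baselines:
                raise InvalidDesignError(f"no baseline distribution for measure {m!r}")
        baseline_tp = self.timepoints[0]
        for (measure, tp, arm), _ in self.effect_sizes.items():
            if tp not in self.timepoints:
                raise InvalidDesignError(
                    f"unknown timepoint {tp!r} in effect_sizes (have {self.timepoints})"
                )
            if tp == baseline_tp:
                raise InvalidDesignError("baseline effects must be zero by construction")
            if measure not in self.measures:
                raise InvalidDesignError(f"unknown measure {measure!r} in effect_sizes")
            if arm not in ("treatment", "control"):
                raise InvalidDesignError(f"unknown arm {arm!r} in effect_sizes")

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.between_subject_sd, self.within_subject_sd))


def simulate_scales(design: TrialDesign) -> pd.DataFrame:
    """Simulate a long-format clinical-scale table for a two-arm trial.

    One row per subject x timepoint x measure with columns ``subject_id``,
    ``arm``, ``timepoint``, ``measure``, ``value``.  Within-subject
    correlation across timepoints comes from a per-(subject, measure) random
    intercept with SD ``between_subject_sd``; residual noise has SD
    ``within_subject_sd``.
    """
    rng = np.random.default_rng(design.seed)
    arms = ["treatment"] * design.n_treatment + ["control"] * design.n_control
    subjects = [f"S{i + 1:02d}" for i in range(len(arms))]
    rows = []
    for subj, arm in zip(subjects, arms):
        for measure in design.measures:
            mean, _, (lo, hi) = design.baselines[measure]
            intercept = rng.normal(0.0, design.between_subject_sd)
            for tp in design.timepoints:
                shift = design.effect_sizes.get((measure, tp, arm), 0.0) * design.total_sd
                value = mean + intercept + shift + rng.normal(0.0, design.within_subject_sd)
                rows.append((subj, arm, tp, measure, float(np.clip(value, lo, hi))))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "timepoint", "measure", "value"])


def simulate_volumes(
    n_subjects: int = N_VBM_SUBJECTS,
    regions: tuple | None = None,
    effect: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Simulate paired baseline / 6-month regional gray-matter volume tables.

    Parameters
    ----------
    regions : tuple of str, optional
        AAL region abbreviations to simulate (default: the nine regions of
        the reference volumetry table).
    effect : dict, optional
        Map region -> fractional change at 6M (e.g. ``{"SOG.L": 0.05}``).
        Fractions must exceed -1.  Unlisted regions are unchanged.
    noise_sd : float
        Measurement noise SD as a fraction of the regional mean, applied
        independently at both timepoints.

    Returns a long-format table (``subject_id``, ``region_index``, ``region``,
    ``timepoint``, ``volume``) including a ``TOTAL`` pseudo-region equal to
    the sum of regional volumes plus a subject-specific unmodelled remainder
    that is constant across timepoints — so regional and total analyses are
    mutually consistent.
    """
    summary = gm_volume_summary().set_index("region")
    if regions is None:
        regions = tuple(AAL_REGIONS.values())
    for r in regions:
        if r not in summary.index or r == "TOTAL":
            raise InvalidRegionError(f"unknown region {r!r} (known: {sorted(AAL_REGIONS.values())})")
    effect = dict(effect or {})
    for r, e in effect.items():
        if r not in regions:
            raise InvalidRegionError(f"effect names unknown region {r!r}")
        if e <= -1:
            raise InvalidRegionError(f"fractional change for {r!r} must be > -1, got {e}")

    rng = np.random.default_rng(seed)
    total_mean = summary.loc["TOTAL", "baseline_mean"]
    total_sd = summary.loc["TOTAL", "baseline_sd"]
    region_means = summary.loc[list(regions), "baseline_mean"].to_numpy()
    region_sds = summary.loc[list(regions), "baseline_sd"].to_numpy()
    remainder_mean = total_mean - region_means.sum()
    # remainder carries the between-subject variance the regions do not
    remainder_sd = float(np.sqrt(max(total_sd**2 - np.sum(region_sds**2), 0.0)))

    rows = []
    for s in range(n_subjects):
        subj = f"V{s + 1:02d}"
        true = np.maximum(rng.normal(region_means, region_sds), 1.0)
        remainder = max(rng.normal(remainder_mean, remainder_sd), 1.0)
        obs = {}
        for tp in ("baseline", "6M"):
            factor = np.array([1.0 + effect.get(r, 0.0) if tp == "6M" else 1.0 for r in regions])
            noise = rng.normal(0.0, noise_sd * region_means)
            obs[tp] = np.maximum(true * factor + noise, 1.0)
            for r, v in zip(regions, obs[tp]):
                idx = int(summary.loc[r, "region_index"])
                rows.append((subj, idx, r, tp, float(v)))
            rows.append((subj, 0, "TOTAL", tp, float(obs[tp].sum() + remainder)))
    return pd.DataFrame(
        rows, columns=["subject_id", "region_index", "region", "timepoint", "volume"]
    )
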