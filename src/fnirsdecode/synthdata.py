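"""Seeded synthetic fNIRS data with known ground truth.

This module generates block-design fNIRS recordings whose statistical
structure matches what the downstream analysis assumes: a 32-channel
two-wavelength montage over fronto-temporal and occipital cortex,
trial schedules for passive (image viewing) and active (affective
imagery) elicitation blocks, hemodynamic-response-shaped oxy-/deoxy-
hemoglobin concentration changes with class-dependent spatial
patterns, physiological noise, and the forward modified Beer-Lambert
projection to optical density.

Everything is deterministic given a seed, and every recording can
carry a reference to the :class:`EffectSpec` that produced it, so
parameter-recovery tests can compare what the decoder finds against
what was planted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

logger = logging.getLogger("fnirsdecode")

#: Default sampling rate of the simulated instrument, Hz.
DEFAULT_FS = 5.2083

#: Laser wavelengths, nm.
WAVELENGTHS_NM = (760, 850)

#: Source-detector separation for contiguous optodes, mm.
SEPARATION_MM = 30.0

#: Differential pathlength factors at 760 and 850 nm.
DEFAULT_DPF = {760: 7.25, 850: 6.38}

#: Molar extinction coefficients of hemoglobin, mM^-1 cm^-1, from the
#: widely used compiled in-vitro spectra (Prahl compilation, version
#: tag "prahl-1998").  Values differ slightly across literature
#: sources; this table is pinned so the forward/inverse Beer-Lambert
#: conversion is exactly reproducible, and it is overridable through
#: :class:`OpticalModel`.
EXTINCTION_MM_CM = {
    ("hbo", 760): 0.5864,
    ("hbr", 760): 1.54852,
    ("hbo", 850): 1.0580,
    ("hbr", 850): 0.69132,
}
EXTINCTION_VERSION = "prahl-1998"

#: Region labels used by the packaged montage.
REGIONS = (
    "lOFC-L", "lOFC-R", "mOFC", "vlPFC-L", "vlPFC-R", "dmPFC",
    "temporal", "occipital-primary", "occipital-association",
)

#: Valence labels.
LABELS = ("positive", "negative", "neutral")

#: Per-block trial counts: 5 positive, 5 negative, 10 neutral.
TRIAL_COUNTS = {"positive": 5, "negative": 5, "neutral": 10}

#: Duration of the analysed epoch within each trial, s.
EPOCH_S = 30.0


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One source-detector pair with its cortical region label."""

    source: int
    detector: int
    region: str

    @property
    def name(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass(frozen=True)
class Montage:
    """Fixed, ordered channel layout; channel order defines feature order."""

    channels: tuple[Channel, ...]
    separation_mm: float = SEPARATION_MM
    wavelengths_nm: tuple[int, int] = WAVELENGTHS_NM

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_sources(self) -> int:
        return len({c.source for c in self.channels})

    @property
    def n_detectors(self) -> int:
        return len({c.detector for c in self.channels})

    @property
    def pathlength_cm(self) -> float:
        return self.separation_mm / 10.0

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def region_of(self, name: str) -> str:
        for c in self.channels:
            if c.name == name:
                return c.region
        raise KeyError(name)


# The packaged layout is a faithful-count stand-in for the experimental
# cap: 9 sources + 9 detectors across the fronto-temporal band (26
# channels, lateral detectors near T7/T8) and 3 + 3 over occipital
# cortex (6 channels).  Channel 5-5 sits at the frontopolar midline
# (Fpz) and channel 11-11 at Oz.
DEFAULT_LAYOUT: tuple[tuple[int, int, str], ...] = (
    (1, 1, "temporal"), (1, 2, "temporal"), (2, 1, "temporal"),
    (2, 2, "lOFC-L"), (2, 3, "lOFC-L"), (3, 2, "lOFC-L"),
    (3, 3, "vlPFC-L"), (3, 4, "vlPFC-L"), (4, 3, "vlPFC-L"),
    (4, 4, "mOFC"), (4, 5, "dmPFC"), (5, 4, "dmPFC"),
    (5, 5, "dmPFC"), (5, 6, "dmPFC"), (6, 5, "dmPFC"),
    (6, 4, "mOFC"), (6, 6, "mOFC"),
    (6, 7, "vlPFC-R"), (7, 6, "vlPFC-R"), (7, 7, "vlPFC-R"),
    (7, 8, "lOFC-R"), (8, 7, "lOFC-R"), (8, 8, "lOFC-R"),
    (8, 9, "temporal"), (9, 8, "temporal"), (9, 9, "temporal"),
    (10, 10, "occipital-association"), (10, 11, "occipital-association"),
    (11, 10, "occipital-association"), (11, 11, "occipital-primary"),
    (11, 12, "occipital-primary"), (12, 11, "occipital-primary"),
)


def build_montage(layout=None, *, strict: bool = True) -> Montage:
    """Build a :class:`Montage` from ``(source, detector, region)`` triples.

    Parameters
    ----------
    layout
        Iterable of ``(source, detector, region)``; defaults to the
        packaged 32-channel layout.
    strict
        When true, require exactly 32 channels (the experimental cap).

    Raises
    ------
    ValueError
        On duplicate source-detector pairs, unknown region labels, or
        (in strict mode) a channel count other than 32.
    """
    if layout is None:
        layout = DEFAULT_LAYOUT
    channels = []
    seen = set()
    for source, detector, region in layout:
        key = (int(source), int(detector))
        if key in seen:
            raise ValueError(f"duplicate channel {source}-{detector}")
        if region not in REGIONS:
            raise ValueError(f"unknown region label {region!r}")
        seen.add(key)
        channels.append(Channel(int(source), int(detector), region))
    if strict and len(channels) != 32:
        raise ValueError(f"expected 32 channels, got {len(channels)}")
    return Montage(channels=tuple(channels))


# --------------------------------------------------------------------------
# Trial schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One trial; ``onset_s`` marks the start of the analysed 30-s epoch."""

    label: str
    onset_s: float
    duration_s: float = EPOCH_S


@dataclass(frozen=True)
class Event:
    time_s: float
    kind: str  # fixation | instruction | stimulus-image | rating | rest
    duration_s: float = 0.0


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trials and events of one elicitation block.

    Per-trial timeline (seconds from trial start):

    * passive — 0-2 fixation; 2-32 image viewing (a new image every
      5 s, six per trial); 32-36 intensity rating; then a 2-4 s rest.
      The analysed epoch is the 30-s viewing period.
    * active — 0-2 fixation; 2-4 instruction cue; 4-34 affective
      imagery (rest with eyes open on neutral trials); 34-38 rating;
      then a 2-4 s rest.  The analysed epoch is the imagery period.

    The rating screen is self-paced in the experiment; the generator
    uses a fixed 4 s.
    """

    condition: str
    trials: tuple[Trial, ...]
    events: tuple[Event, ...]
    seed: int

    @property
    def end_s(self) -> float:
        return max(e.time_s + e.duration_s for e in self.events)

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]


#: Time (s) from trial start to the analysed epoch, per condition:
#: passive epochs start at image onset, active epochs at the end of
#: the instruction cue.
EPOCH_DELAY_S = {"passive": 2.0, "active": 4.0}

_FIXATION_S = 2.0
_INSTRUCTION_S = 2.0
_RATING_S = 4.0
_IMAGE_SPACING_S = 5.0
_N_IMAGES = 6
_REST_RANGE_S = (2.0, 4.0)


def _draw_label_order(rng: np.random.Generator, max_tries: int = 10000) -> list[str]:
    """Random order of 5/5/10 labels with no positive-negative adjacency."""
    base = (["positive"] * TRIAL_COUNTS["positive"]
            + ["negative"] * TRIAL_COUNTS["negative"]
            + ["neutral"] * TRIAL_COUNTS["neutral"])
    for _ in range(max_tries):
        order = [str(x) for x in rng.permutation(base)]
        ok = all(not ({a, b} == {"positive", "negative"})
                 for a, b in zip(order, order[1:]))
        if ok:
            return order
    raise RuntimeError("could not draw a valid trial order")  # pragma: no cover


def make_schedule(condition: str, seed: int) -> TrialSchedule:
    """Generate one block's randomized trial schedule.

    Trial order is drawn by seeded rejection sampling until no positive
    trial is adjacent to a negative one (a neutral trial always
    separates them).  Inter-trial rest durations are uniform on [2, 4] s.
    """
    if condition not in ("passive", "active"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    order = _draw_label_order(rng)
    rests = rng.uniform(*_REST_RANGE_S, size=len(order))

    trials: list[Trial] = []
    events: list[Event] = []
    t = 0.0
    for label, rest in zip(order, rests):
        events.append(Event(t, "fixation", _FIXATION_S))
        cursor = t + _FIXATION_S
        if condition == "active":
            events.append(Event(cursor, "instruction", _INSTRUCTION_S))
            cursor += _INSTRUCTION_S
        epoch_onset = t + EPOCH_DELAY_S[condition]
        if condition == "passive":
            for k in range(_N_IMAGES):
                events.append(Event(epoch_onset + k * _IMAGE_SPACING_S,
                                    "stimulus-image", _IMAGE_SPACING_S))
        trials.append(Trial(label, epoch_onset, EPOCH_S))
        cursor = epoch_onset + EPOCH_S
        events.append(Event(cursor, "rating", _RATING_S))
        cursor += _RATING_S
        events.append(Event(cursor, "rest", float(rest)))
        t = cursor + float(rest)
    return TrialSchedule(condition=condition, trials=tuple(trials),
                         events=tuple(events), seed=int(seed))


# --------------------------------------------------------------------------
# Effect, noise and optical specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters.

    ``peak_s`` and ``undershoot_s`` are the shape parameters (modes at
    ``peak_s - 1`` s and ``undershoot_s - 1`` s for unit scale);
    ``ratio`` is the peak-to-undershoot amplitude ratio.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 6.0
    length_s: float = 32.0

    def kernel(self, fs: float) -> np.ndarray:
        """Sampled HRF, normalized to unit peak."""
        t = np.arange(0.0, self.length_s, 1.0 / fs)
        h = (_stats.gamma.pdf(t, self.peak_s)
             - _stats.gamma.pdf(t, self.undershoot_s) / self.ratio)
        return h / h.max()


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-region, per-label hemodynamic amplitudes (µM).

    ``amplitudes[region][label]`` is an ``(hbo, hbr)`` pair giving the
    plateau concentration change for one trial of that label over
    channels in that region.  ``jitter_cv`` is the coefficient of
    variation of a multiplicative trial-to-trial gain (shared across
    channels within a trial, emulating arousal/attention fluctuation).
    With ``workspace_mode`` the positive and negative labels share one
    spatial pattern (the affective-workspace structure); without it
    the negative pattern is sign-flipped (a bipolar-code structure).
    """

    amplitudes: dict[str, dict[str, tuple[float, float]]]
    hrf: HRFParams = HRFParams()
    jitter_cv: float = 0.2
    workspace_mode: bool = True

    def __post_init__(self):
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        for region, per_label in self.amplitudes.items():
            for label, pair in per_label.items():
                if not all(math.isfinite(v) for v in pair):
                    raise ValueError(f"non-finite amplitude for {region}/{label}")
        if self.workspace_mode:
            cs = self.contrast_cosine()
            if cs is not None and cs <= 0.9:
                raise ValueError(
                    f"workspace_mode requires cosine similarity > 0.9 between "
                    f"positive and negative contrasts, got {cs:.3f}")

    def amplitude(self, region: str, label: str) -> tuple[float, float]:
        return self.amplitudes.get(region, {}).get(label, (0.0, 0.0))

    def contrast_cosine(self) -> float | None:
        """Cosine similarity of the (pos-neu) and (neg-neu) HbO contrasts."""
        pos = np.array([self.amplitude(r, "positive")[0]
                        - self.amplitude(r, "neutral")[0] for r in REGIONS])
        neg = np.array([self.amplitude(r, "negative")[0]
                        - self.amplitude(r, "neutral")[0] for r in REGIONS])
        np_, nn = np.linalg.norm(pos), np.linalg.norm(neg)
        if np_ == 0 or nn == 0:
            return None
        return float(pos @ neg / (np_ * nn))

    # -- factories ---------------------------------------------------------

    @staticmethod
    def null() -> "EffectSpec":
        """Zero planted effect everywhere."""
        return EffectSpec(amplitudes={}, workspace_mode=False)

    @staticmethod
    def default(condition: str = "passive", scale: float = 1.0,
                workspace_mode: bool = True, jitter_cv: float = 0.2,
                hbr_ratio: float = -1.0 / 3.0) -> "EffectSpec":
        """Study-condition effect patterns.

        Affective (positive/negative) trials activate an orbitofrontal/
        ventrolateral prefrontal pattern with a deactivation over dmPFC
        and a modest occipital arousal component.  Passive blocks add a
        visual response over occipital channels on *every* trial
        (images are on screen regardless of valence); active neutral
        trials are rest and carry no planted effect.  The two
        conditions share the prefrontal core but differ in gains and in
        the occipital component, so condition is itself decodable.
        Amplitudes are in µM HbO; HbR is ``hbr_ratio`` times HbO
        (anticorrelated neurovascular coupling).
        """
        if condition == "passive":
            affect = {"lOFC-L": 0.40, "lOFC-R": 0.40, "mOFC": 0.25,
                      "vlPFC-L": 0.25, "vlPFC-R": 0.25, "dmPFC": -0.30,
                      "occipital-primary": 0.15, "occipital-association": 0.15}
            base = {"occipital-primary": 0.30, "occipital-association": 0.20}
        elif condition == "active":
            affect = {"lOFC-L": 0.15, "lOFC-R": 0.35, "mOFC": 0.40,
                      "vlPFC-L": 0.15, "vlPFC-R": 0.40, "dmPFC": -0.30,
                      "occipital-primary": 0.25, "occipital-association": 0.30}
            base = {}
        else:
            raise ValueError(f"unknown condition {condition!r}")

        def pair(hbo: float) -> tuple[float, float]:
            return (hbo * scale, hbo * scale * hbr_ratio)

        amplitudes: dict[str, dict[str, tuple[float, float]]] = {}
        for region in REGIONS:
            per = {}
            a = affect.get(region, 0.0)
            b = base.get(region, 0.0)
            per["positive"] = pair(b + a)
            per["negative"] = pair(b + (a if workspace_mode else -a))
            per["neutral"] = pair(b)
            amplitudes[region] = per
        return EffectSpec(amplitudes=amplitudes, jitter_cv=jitter_cv,
                          workspace_mode=workspace_mode)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for simulated concentrations (µM).

    Physiological oscillations (cardiac, respiratory, Mayer waves) are
    narrowband processes with a phase random walk: each channel's
    oscillator drifts in phase with coherence time ``coherence_s``,
    as real physiological rhythms do.  Finite coherence also keeps
    trials far apart in time statistically exchangeable, which a
    block-long fixed-phase sinusoid would not.  The linear drift slope
    is drawn per channel with standard deviation ``drift_slope_sd``
    (µM/s); it defaults to zero because a deterministic monotone trend
    makes trial order informative and inflates leave-one-trial-out
    accuracy even with no planted effect (see docs/methods.md) — set
    it nonzero to study exactly that confound.  Any oscillator
    frequency at or above the Nyquist rate raises an error rather than
    silently aliasing.
    """

    white_sd: float = 0.3
    cardiac: tuple[float, float] = (1.2, 0.15)       # (Hz, µM)
    respiratory: tuple[float, float] = (0.3, 0.15)
    mayer: tuple[float, float] = (0.1, 0.15)
    drift_slope_sd: float = 0.0
    coherence_s: float = 15.0

    def __post_init__(self):
        for name in ("cardiac", "respiratory", "mayer"):
            freq, amp = getattr(self, name)
            if freq <= 0:
                raise ValueError(f"{name} frequency must be > 0")
            if amp < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
        if self.white_sd < 0 or self.drift_slope_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.coherence_s <= 0:
            raise ValueError("coherence_s must be > 0")

    def validate_for_fs(self, fs: float) -> None:
        for name in ("cardiac", "respiratory", "mayer"):
            freq, _ = getattr(self, name)
            if freq >= fs / 2:
                raise ValueError(
                    f"{name} frequency {freq} Hz is at or above Nyquist "
                    f"({fs / 2:.4g} Hz); it would alias")

    @staticmethod
    def silent() -> "NoiseSpec":
        return NoiseSpec(white_sd=0.0, cardiac=(1.2, 0.0),
                         respiratory=(0.3, 0.0), mayer=(0.1, 0.0),
                         drift_slope_sd=0.0)


@dataclass(frozen=True)
class OpticalModel:
    """Extinction coefficients, DPFs and pathlength for the Beer-Lambert
    conversion.  Extinction units mM^-1 cm^-1; pathlength cm."""

    extinction: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(EXTINCTION_MM_CM))
    dpf: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DPF))
    pathlength_cm: float = SEPARATION_MM / 10.0
    version: str = EXTINCTION_VERSION

    def eps(self, chromophore: str, wavelength: int) -> float:
        try:
            return self.extinction[(chromophore, wavelength)]
        except KeyError:
            raise KeyError(
                f"no extinction coefficient for {chromophore} at "
                f"{wavelength} nm") from None

    def forward_matrix(self, wavelengths=WAVELENGTHS_NM) -> np.ndarray:
        """2x2 matrix A with ΔOD(λ) = A @ (ΔHbO, ΔHbR) in mM."""
        return np.array([
            [self.eps("hbo", wl) * self.dpf[wl] * self.pathlength_cm,
             self.eps("hbr", wl) * self.dpf[wl] * self.pathlength_cm]
            for wl in wavelengths])

    def check_invertible(self, wavelengths=WAVELENGTHS_NM,
                         max_cond: float = 1e12) -> None:
        cond = np.linalg.cond(self.forward_matrix(wavelengths))
        if not np.isfinite(cond) or cond > max_cond:
            raise ValueError(
                f"extinction matrix is singular (condition number {cond:g})")


# --------------------------------------------------------------------------
# Recordings
# --------------------------------------------------------------------------

@dataclass
class ConcentrationRecording:
    """Per-channel HbO/HbR concentration-change series, µM.

    ``hbo`` and ``hbr`` are (n_channels, n_samples) arrays.
    """

    fs: float
    hbo: np.ndarray
    hbr: np.ndarray
    montage: Montage
    schedule: TrialSchedule | None = None
    ground_truth: EffectSpec | None = None

    def __post_init__(self):
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR arrays must share shape")
        if self.hbo.shape[0] != self.montage.n_channels:
            raise ValueError("channel count mismatch with montage")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RawRecording:
    """Optical-density series per channel and wavelength.

    ``od`` has shape (n_channels, 2, n_samples); axis 1 follows
    ``montage.wavelengths_nm`` order.
    """

    fs: float
    od: np.ndarray
    montage: Montage
    schedule: TrialSchedule | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.od.ndim != 3 or self.od.shape[1] != len(self.montage.wavelengths_nm):
            raise ValueError("od must be (n_channels, n_wavelengths, n_samples)")
        if self.od.shape[0] != self.montage.n_channels:
            raise ValueError("channel count mismatch with montage")

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

#: Padding appended after the last event so the final epoch and filter
#: edges stay inside the recording, s.
RECORDING_PAD_S = 10.0


def simulate_concentrations(schedule: TrialSchedule, montage: Montage,
                            effect_spec: EffectSpec, noise_spec: NoiseSpec,
                            seed: int, fs: float = DEFAULT_FS,
                            ) -> ConcentrationRecording:
    """Simulate one block's HbO/HbR concentration series.

    Each trial contributes a 30-s boxcar convolved with the canonical
    double-gamma HRF (normalized so the plateau of the convolved
    response is 1), scaled by the region- and label-specific amplitude
    and a per-trial multiplicative gain with coefficient of variation
    ``effect_spec.jitter_cv``.  White noise, cardiac/respiratory/Mayer
    oscillations with per-channel random phases, and per-channel linear
    drift are added on top.
    """
    noise_spec.validate_for_fs(fs)
    rng = np.random.default_rng(seed)
    n = int(math.ceil((schedule.end_s + RECORDING_PAD_S) * fs))
    n_ch = montage.n_channels
    t = np.arange(n) / fs

    # Per-trial regressors: boxcar * HRF, unit plateau.  The gain jitter
    # is drawn independently per (trial, channel) — local vascular
    # variability — and shared between the channel's two chromophores.
    kernel = effect_spec.hrf.kernel(fs)
    box_len = int(round(EPOCH_S * fs))
    plateau = np.convolve(np.ones(box_len), kernel).max()
    jitter = 1.0 + effect_spec.jitter_cv * rng.standard_normal(
        (len(schedule.trials), n_ch))

    # One regressor per (label, channel); trials superpose linearly.
    reg = np.zeros((len(LABELS), n_ch, n))
    for li, label in enumerate(LABELS):
        box = np.zeros((n_ch, n))
        for ti, trial in enumerate(schedule.trials):
            if trial.label != label:
                continue
            if trial.duration_s < 0:
                raise ValueError("negative trial duration")
            i0 = int(math.floor(trial.onset_s * fs))
            i1 = i0 + int(round(trial.duration_s * fs))
            if i1 > n:
                raise ValueError("trial epoch extends past recording end")
            box[:, i0:i1] = jitter[ti][:, None]
        reg[li] = _signal.fftconvolve(box, kernel[None, :],
                                      axes=1)[:, :n] / plateau

    amp_hbo = np.array([[effect_spec.amplitude(ch.region, label)[0]
                         for label in LABELS] for ch in montage.channels])
    amp_hbr = np.array([[effect_spec.amplitude(ch.region, label)[1]
                         for label in LABELS] for ch in montage.channels])
    hbo = np.einsum("kl,lkn->kn", amp_hbo, reg)
    hbr = np.einsum("kl,lkn->kn", amp_hbr, reg)

    # Physiological oscillations: phase-random-walk narrowband processes
    # per channel; HbR carries the anticorrelated counterpart (-1/3
    # gain) of the same waveform.
    dt = 1.0 / fs
    for freq, amp in (noise_spec.cardiac, noise_spec.respiratory,
                      noise_spec.mayer):
        if amp == 0:
            continue
        sig = math.sqrt(2.0 / noise_spec.coherence_s)
        dphi = (2 * np.pi * freq * dt
                + sig * math.sqrt(dt) * rng.standard_normal((n_ch, n)))
        phi = np.cumsum(dphi, axis=1) + rng.uniform(0, 2 * np.pi, (n_ch, 1))
        wave = amp * np.sin(phi)
        hbo += wave
        hbr += -wave / 3.0

    if noise_spec.drift_slope_sd > 0:
        slopes = noise_spec.drift_slope_sd * rng.standard_normal(n_ch)
        drift = slopes[:, None] * (t - t.mean())[None, :]
        hbo += drift
        hbr += -drift / 3.0

    if noise_spec.white_sd > 0:
        hbo = hbo + noise_spec.white_sd * rng.standard_normal((n_ch, n))
        hbr = hbr + noise_spec.white_sd * rng.standard_normal((n_ch, n))

    return ConcentrationRecording(fs=fs, hbo=hbo, hbr=hbr, montage=montage,
                                  schedule=schedule, ground_truth=effect_spec)


def concentrations_to_od(conc: ConcentrationRecording,
                         optical_model: OpticalModel | None = None,
                         seed: int | None = None) -> RawRecording:
    """Forward modified Beer-Lambert projection to optical density.

    For each channel and wavelength λ::

        ΔOD(λ, t) = [ε(HbO, λ) ΔHbO(t) + ε(HbR, λ) ΔHbR(t)] · L · DPF(λ)

    with concentrations in mM (the stored µM series are divided by
    1000), ε in mM^-1 cm^-1 and the pathlength L in cm, so ΔOD is
    dimensionless.
    """
    model = optical_model if optical_model is not None else OpticalModel()
    model.check_invertible(conc.montage.wavelengths_nm)
    A = model.forward_matrix(conc.montage.wavelengths_nm)  # (2, 2)
    conc_mm = np.stack([conc.hbo, conc.hbr], axis=1) * 1e-3  # (ch, 2, n)
    od = np.einsum("lc,kcn->kln", A, conc_mm)
    return RawRecording(fs=conc.fs, od=od, montage=conc.montage,
                        schedule=conc.schedule, seed=seed)


def simulate_block(condition: str, seed: int, montage: Montage | None = None,
                   effect_spec: EffectSpec | None = None,
                   noise_spec: NoiseSpec | None = None,
                   optical_model: OpticalModel | None = None,
                   fs: float = DEFAULT_FS) -> RawRecording:
    """Convenience wrapper: schedule -> concentrations -> optical density.

    The schedule and the signal simulation use seeds derived from
    ``seed`` so one integer reproduces the whole block.
    """
    montage = montage if montage is not None else build_montage()
    if effect_spec is None:
        effect_spec = EffectSpec.default(condition)
    noise_spec = noise_spec if noise_spec is not None else NoiseSpec()
    ss = np.random.SeedSequence([int(seed), 0 if condition == "passive" else 1])
    sched_seed, sim_seed = (int(s) % (2 ** 31) for s in
                            ss.generate_state(2, dtype=np.uint64))
    schedule = make_schedule(condition, sched_seed)
    conc = simulate_concentrations(schedule, montage, effect_spec,
                                   noise_spec, sim_seed, fs=fs)
    return concentrations_to_od(conc, optical_model, seed=seed)
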