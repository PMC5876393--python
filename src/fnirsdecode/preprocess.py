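"""Optical-density preprocessing: band-pass filtering, whole-record
baselining, modified Beer-Lambert conversion, and trial segmentation.

The pipeline order is fixed: filter -> baseline -> convert -> segment.
Filtering is zero-phase (forward-backward FIR) so epoch features stay
aligned with event onsets; the baseline step subtracts the whole-record
mean of each (channel, wavelength) series, which after band-pass
filtering is nearly a no-op but is kept as an explicit stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .synthdata import (ConcentrationRecording, OpticalModel, RawRecording,
                        TrialSchedule, EPOCH_S)

logger = logging.getLogger("fnirsdecode")

#: Band edges of the default band-pass, Hz.
DEFAULT_BAND = (0.01, 0.2)

#: Default FIR length; odd (type-I linear phase).  At fs = 5.2083 Hz the
#: 0.01 Hz low edge needs a long filter: 1001 taps put the stopband
#: about -49 dB at DC (a single pass) while shorter designs leak DC
#: badly (501 taps: only -15 dB).
DEFAULT_N_TAPS = 1001


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR band-pass; ``taps`` are exactly symmetric."""

    fs: float
    low_cut: float
    high_cut: float
    taps: np.ndarray

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    def response_db(self, freqs) -> np.ndarray:
        """Magnitude response in dB at the given frequencies (Hz)."""
        _, h = _signal.freqz(self.taps, worN=np.atleast_1d(freqs), fs=self.fs)
        return 20 * np.log10(np.maximum(np.abs(h), 1e-300))


def design_fir(fs: float, low_cut: float = DEFAULT_BAND[0],
               high_cut: float = DEFAULT_BAND[1],
               n_taps: int = DEFAULT_N_TAPS) -> FilterSpec:
    """Design the linear-phase FIR band-pass (Hamming-windowed sinc).

    ``n_taps`` must be odd (type-I symmetry, so a band-pass is
    realizable and taps(k) == taps(n-1-k) exactly).
    """
    if not (0 < low_cut < high_cut < fs / 2):
        raise ValueError(
            f"band ({low_cut}, {high_cut}) Hz invalid for fs = {fs} Hz")
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd for a type-I linear-phase FIR")
    taps = _signal.firwin(n_taps, [low_cut, high_cut], pass_zero=False, fs=fs)
    taps = 0.5 * (taps + taps[::-1])  # enforce exact tap symmetry
    return FilterSpec(fs=fs, low_cut=low_cut, high_cut=high_cut, taps=taps)


def apply_filter(raw: RawRecording, filter_spec: FilterSpec) -> RawRecording:
    """Zero-phase (forward-backward) filtering of every OD series.

    Output length equals input length.  Because the filter runs
    forward and backward, its effective magnitude response is the
    square of the designed one and no time shift is introduced.
    """
    if raw.n_samples <= 3 * filter_spec.n_taps:
        raise ValueError(
            f"series of {raw.n_samples} samples too short for a "
            f"{filter_spec.n_taps}-tap zero-phase filter")
    od = _signal.filtfilt(filter_spec.taps, [1.0], raw.od, axis=-1)
    return replace(raw, od=od)


def baseline_whole_record(raw: RawRecording) -> RawRecording:
    """Subtract each (channel, wavelength) series' whole-record mean."""
    if raw.n_samples == 0:
        raise ValueError("empty series")
    od = raw.od - raw.od.mean(axis=-1, keepdims=True)
    return replace(raw, od=od)


def od_to_concentration(raw: RawRecording,
                        optical_model: OpticalModel | None = None,
                        ) -> ConcentrationRecording:
    """Inverse modified Beer-Lambert: solve for ΔHbO/ΔHbR in µM.

    Per channel and sample the 2x2 system
    ``ΔOD(λ) = Σ_c ε(c, λ) ΔC_c L DPF(λ)`` is solved for the two
    chromophores; the mM solution is scaled to µM.
    """
    model = optical_model if optical_model is not None else OpticalModel()
    wavelengths = raw.montage.wavelengths_nm
    if raw.od.shape[1] != len(wavelengths):
        raise ValueError("missing wavelength series")
    model.check_invertible(wavelengths)
    A = model.forward_matrix(wavelengths)
    conc_mm = np.einsum("cl,kln->kcn", np.linalg.inv(A), raw.od)
    conc_um = conc_mm * 1e3
    return ConcentrationRecording(fs=raw.fs, hbo=conc_um[:, 0], hbr=conc_um[:, 1],
                                  montage=raw.montage, schedule=raw.schedule)


@dataclass(frozen=True)
class Epoch:
    """One trial's 30-s window of HbO/HbR samples, channels in montage order."""

    label: str
    condition: str
    onset_s: float
    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    fs: float

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]


def epoch_samples(fs: float, duration_s: float = EPOCH_S) -> int:
    """Samples per epoch: floor(duration * fs); 156 at 5.2083 Hz."""
    return int(math.floor(duration_s * fs))


def segment(conc: ConcentrationRecording,
            schedule: TrialSchedule | None = None) -> list[Epoch]:
    """Cut the concentration series into labelled 30-s trial epochs.

    Windows are half-open ``[onset, onset + 30)`` with the floor
    convention for time-to-sample conversion, so every epoch has
    exactly ``floor(30 fs)`` samples.
    """
    if schedule is None:
        schedule = conc.schedule
    if schedule is None:
        raise ValueError("no schedule attached or provided")
    n_epoch = epoch_samples(conc.fs)
    epochs = []
    for trial in schedule.trials:
        if not trial.label:
            raise ValueError("trial without label")
        i0 = int(math.floor(trial.onset_s * conc.fs))
        i1 = i0 + n_epoch
        if i0 < 0 or i1 > conc.n_samples:
            raise ValueError(
                f"epoch [{trial.onset_s}, {trial.onset_s + EPOCH_S}) s out of "
                f"recording bounds")
        epochs.append(Epoch(label=trial.label, condition=schedule.condition,
                            onset_s=trial.onset_s,
                            hbo=conc.hbo[:, i0:i1].copy(),
                            hbr=conc.hbr[:, i0:i1].copy(), fs=conc.fs))
    return epochs


def preprocess_block(raw: RawRecording,
                     filter_spec: FilterSpec | None = None,
                     optical_model: OpticalModel | None = None,
                     schedule: TrialSchedule | None = None) -> list[Epoch]:
    """Run the fixed preprocessing chain on one block.

    Order: band-pass filter the OD series, baseline by the whole
    record, convert to chromophore concentrations, segment into the
    30-s trial epochs.
    """
    if filter_spec is None:
        filter_spec = design_fir(raw.fs)
    filtered = apply_filter(raw, filter_spec)
    baselined = baseline_whole_record(filtered)
    conc = od_to_concentration(baselined, optical_model)
    return segment(conc, schedule)
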