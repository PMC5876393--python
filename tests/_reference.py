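"""Independent brute-force reference implementations used as oracles.

These deliberately re-derive results through different code paths
(explicit loops, direct formula evaluation, scipy.linalg solves) so
they can check the package without sharing its implementation.
"""

import numpy as np
import scipy.linalg
from scipy import stats as sstats


def moving_average_loop(series, fs, window_s=2.0, overlap=0.5):
    """Windowed means via an explicit python loop."""
    series = np.asarray(series, dtype=float)
    wl = int(np.floor(window_s * fs))
    hop = int(round(wl * (1.0 - overlap)))
    out = []
    start = 0
    while start + wl <= len(series):
        out.append(series[start:start + wl].sum() / wl)
        start += hop
    return np.array(out)


def dtft_magnitude(taps, freq, fs):
    """|H(f)| by the direct discrete-time Fourier sum."""
    k = np.arange(len(taps))
    return abs(np.sum(taps * np.exp(-2j * np.pi * freq * k / fs)))


def double_gamma_hrf(t, peak=6.0, undershoot=16.0, ratio=6.0):
    """Canonical double-gamma HRF evaluated directly from gamma pdfs."""
    h = sstats.gamma.pdf(t, peak) - sstats.gamma.pdf(t, undershoot) / ratio
    return h / h.max()


def convolved_boxcar_response(fs, onset_s, duration_s, n_samples,
                              hrf_kwargs=None):
    """Unit-plateau trial response by direct numerical convolution."""
    hrf_kwargs = hrf_kwargs or {}
    t = np.arange(0.0, 32.0, 1.0 / fs)
    kernel = double_gamma_hrf(t, **hrf_kwargs)
    box = np.zeros(n_samples)
    i0 = int(np.floor(onset_s * fs))
    i1 = i0 + int(round(duration_s * fs))
    box[i0:i1] = 1.0
    full = np.convolve(box, kernel)[:n_samples]
    plateau = np.convolve(np.ones(i1 - i0), kernel).max()
    return full / plateau


def lda_explicit(T, labels, classes, gamma):
    """Shrinkage LDA by explicit per-class covariance computation.

    Returns (w, b).  Uses np.cov and scipy.linalg.solve rather than
    the package's pooled cross-product path.
    """
    T = np.asarray(T, dtype=float)
    y = np.asarray(labels)
    a, b_ = classes
    XA, XB = T[y == a], T[y == b_]
    nA, nB = len(XA), len(XB)
    n, p = T.shape
    mA, mB = XA.mean(axis=0), XB.mean(axis=0)
    SA = np.cov(XA.T, ddof=1) if nA > 1 else np.zeros((p, p))
    SB = np.cov(XB.T, ddof=1) if nB > 1 else np.zeros((p, p))
    S = ((nA - 1) * np.atleast_2d(SA) + (nB - 1) * np.atleast_2d(SB)) / (n - 2)
    Sg = (1 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
    w = scipy.linalg.solve(Sg, mB - mA, assume_a="sym")
    grand = (nA * mA + nB * mB) / n
    return w, -float(w @ grand)


def loto_predictions_explicit(values, labels, classes, gamma):
    """Leave-one-out predictions via the explicit-solve LDA reference."""
    values = np.asarray(values, dtype=float)
    m = len(labels)
    preds = []
    for i in range(m):
        keep = [j for j in range(m) if j != i]
        T = values[keep]
        yT = [labels[j] for j in keep]
        mu = T.mean(axis=0)
        sd = T.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Tn = (T - mu) / sd
        tn = (values[i] - mu) / sd
        w, b = lda_explicit(Tn, yT, classes, gamma)
        preds.append(classes[1] if w @ tn + b > 0 else classes[0])
    return preds
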