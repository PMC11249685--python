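"""Spectral pre-processing operators and the two fixed modality chains.

Raman chain:    5th-order iterative polynomial baseline correction →
                6-level Haar wavelet de-noising → rubber-band baseline
                correction → vector normalization.
NIR-SWIR chain: 1st derivative (w.r.t. wavenumber) → Savitzky-Golay
                smoothing (order 2, 9 points) → rubber-band baseline
                correction → 6-level Haar wavelet de-noising → vector
                normalization.

Every operator preserves vector length and axis. Each chain emits a
ChainTrace recording the ordered steps, their parameters and per-step
input/output checksums for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .spectrum import NIRSWIR, RAMAN, Spectrum


@dataclass(frozen=True)
class PreprocessStep:
    """One named operator application with its full parameter set."""

    name: str
    params: dict


@dataclass
class StepRecord:
    step: PreprocessStep
    input_checksum: str
    output_checksum: str
    note: str = ""


@dataclass
class ChainTrace:
    """Ordered provenance record of a preprocessing chain."""

    records: list[StepRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def step_names(self) -> list[str]:
        return [r.step.name for r in self.records]


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(values, dtype=np.float64).tobytes()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# individual operators
# ---------------------------------------------------------------------------


def poly_baseline_correct(
    spectrum: Spectrum,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Spectrum:
    """Iterative modified-polyfit background subtraction.

    Fits an ``order``-degree polynomial, clips the working signal to the
    fit wherever it lies above it (so peaks stop attracting the fit), and
    refits until the working signal changes by less than ``tol`` in
    relative L2 norm or ``max_iter`` iterations. Returns the input minus
    the final fitted background. A plain least-squares fit would subtract
    peak mass; the iteration converges onto the slowly varying floor.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    n = spectrum.n_points
    if n <= order + 1:
        raise ValueError(
            f"poly_baseline_correct needs more than order+1={order + 1} points"
            f" (got {n})"
        )
    x = spectrum.wavenumbers
    # orthonormal polynomial basis on the (scaled) axis; the background fit
    # each iteration is then a single projection Q (Q^T y).
    t = (x - x.min()) / (x.max() - x.min()) * 2.0 - 1.0
    V = np.polynomial.polynomial.polyvander(t, order)
    Q, _ = np.linalg.qr(V)

    y_work = spectrum.intensities.copy()
    fit = Q @ (Q.T @ y_work)
    for _ in range(max_iter):
        y_new = np.minimum(y_work, fit)
        denom = np.linalg.norm(y_work)
        change = np.linalg.norm(y_new - y_work) / denom if denom > 0 else 0.0
        y_work = y_new
        fit = Q @ (Q.T @ y_work)
        if change < tol:
            break
    return spectrum.with_intensities(spectrum.intensities - fit)


def wavelet_denoise(
    spectrum: Spectrum, levels: int = 6, wavelet: str = "haar"
) -> Spectrum:
    """Multilevel wavelet shrinkage with soft universal thresholding.

    Decomposes to ``levels`` with symmetric signal extension, estimates the
    noise scale from the median absolute deviation of the finest-level
    detail coefficients, soft-thresholds all detail coefficients at
    sigma * sqrt(2 ln n), and reconstructs to the original length.
    """
    n = spectrum.n_points
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n, w.dec_len)
    if levels < 1 or levels > max_level:
        raise ValueError(
            f"cannot decompose {n} points to level {levels} with "
            f"{wavelet!r} (max level {max_level})"
        )
    coeffs = pywt.wavedec(spectrum.intensities, w, mode="symmetric", level=levels)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6744897501960817
    threshold = sigma * np.sqrt(2.0 * np.log(n))
    if threshold > 0:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:  # noise-free signal: nothing to shrink
        denoised = coeffs
    rec = pywt.waverec(denoised, w, mode="symmetric")
    return spectrum.with_intensities(rec[:n])


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (x, y), evaluated at every x (ascending x)."""
    hull = [0]
    for i in range(1, x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j->i
            if (y[k] - y[j]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[k] - x[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def rubberband_correct(spectrum: Spectrum) -> Spectrum:
    """Rubber-band baseline correction: subtract the lower convex hull.

    Anchors the first and last points of the spectrum to zero exactly; all
    other points are non-negative up to rounding (a sampled point can never
    lie below the hull).
    """
    x = spectrum.wavenumbers
    y = spectrum.intensities
    ascending = x[0] < x[-1]
    xs = x if ascending else x[::-1]
    ys = y if ascending else y[::-1]
    baseline = _lower_hull_baseline(xs, ys)
    out = ys - baseline
    out[0] = 0.0
    out[-1] = 0.0
    if not ascending:
        out = out[::-1]
    return spectrum.with_intensities(out)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm; direction is preserved."""
    norm = np.linalg.norm(spectrum.intensities)
    if norm == 0.0:
        raise ValueError(
            "cannot vector-normalize an all-zero spectrum (undefined direction)"
        )
    return spectrum.with_intensities(spectrum.intensities / norm)


def first_derivative(spectrum: Spectrum) -> Spectrum:
    """Derivative with respect to wavenumber (not array index).

    Central differences in the interior, one-sided at the ends; constant
    offsets map to zero and the sign convention is consistent for
    descending axes.
    """
    if spectrum.n_points < 3:
        raise ValueError("first_derivative needs at least 3 points")
    d = np.gradient(spectrum.intensities, spectrum.wavenumbers)
    # a constant input must map to exact zeros, not to rounding residue
    y_scale = np.abs(spectrum.intensities).max()
    h_min = np.abs(np.diff(spectrum.wavenumbers)).min()
    bound = 8.0 * np.finfo(float).eps * y_scale / h_min
    if np.all(np.abs(d) <= bound):
        d = np.zeros_like(d)
    return spectrum.with_intensities(d)


def sg_smooth(
    spectrum: Spectrum, poly_order: int = 2, window: int = 9
) -> Spectrum:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window <= poly_order:
        raise ValueError("Savitzky-Golay window must exceed poly_order")
    if spectrum.n_points < window:
        raise ValueError(
            f"spectrum has {spectrum.n_points} points; window {window} needs"
            " at least that many"
        )
    sm = savgol_filter(spectrum.intensities, window, poly_order)
    return spectrum.with_intensities(sm)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

#: Pre-normalization signal norms below this (relative to input norm) are
#: flagged in the trace as background-dominated.
_NEAR_ZERO_SIGNAL = 1e-8


def _apply(
    spectrum: Spectrum,
    trace: ChainTrace,
    name: str,
    func,
    note: str = "",
    **params,
) -> Spectrum:
    before = _checksum(spectrum.intensities)
    out = func(spectrum, **params)
    trace.records.append(
        StepRecord(PreprocessStep(name, dict(params)), before,
                   _checksum(out.intensities), note)
    )
    return out


def preprocess_raman(spectrum: Spectrum) -> tuple[Spectrum, ChainTrace]:
    """Fixed Raman chain; returns the processed spectrum and its trace."""
    if spectrum.modality != RAMAN:
        raise ValueError("preprocess_raman requires a Raman spectrum")
    trace = ChainTrace()
    s = _apply(spectrum, trace, "poly_baseline", poly_baseline_correct, order=5)
    s = _apply(s, trace, "wavelet_denoise", wavelet_denoise,
               levels=6, wavelet="haar")
    s = _apply(s, trace, "rubberband", rubberband_correct)
    _flag_if_degenerate(s, spectrum, trace)
    s = _apply(s, trace, "vector_normalize", vector_normalize)
    return s, trace


def preprocess_nirswir(spectrum: Spectrum) -> tuple[Spectrum, ChainTrace]:
    """Fixed NIR-SWIR chain; returns the processed spectrum and its trace.

    The derivative is taken with respect to wavenumber; derivative and
    smoothing are two separate stages in the stated order.
    """
    if spectrum.modality != NIRSWIR:
        raise ValueError("preprocess_nirswir requires a NIRSWIR spectrum")
    trace = ChainTrace()
    s = _apply(spectrum, trace, "first_derivative", first_derivative)
    s = _apply(s, trace, "sg_smooth", sg_smooth, poly_order=2, window=9)
    s = _apply(s, trace, "rubberband", rubberband_correct)
    s = _apply(s, trace, "wavelet_denoise", wavelet_denoise,
               levels=6, wavelet="haar")
    _flag_if_degenerate(s, spectrum, trace)
    s = _apply(s, trace, "vector_normalize", vector_normalize)
    return s, trace


def _flag_if_degenerate(
    current: Spectrum, original: Spectrum, trace: ChainTrace
) -> None:
    ref = np.linalg.norm(original.intensities)
    if ref > 0 and np.linalg.norm(current.intensities) < _NEAR_ZERO_SIGNAL * ref:
        trace.records[-1].note = (
            trace.records[-1].note + " pre-normalization signal near machine"
            " scale; output is noise-dominated"
        ).strip()


CHAINS = {RAMAN: preprocess_raman, NIRSWIR: preprocess_nirswir}


def preprocess(spectrum: Spectrum) -> tuple[Spectrum, ChainTrace]:
    """Dispatch to the modality's fixed chain."""
    return CHAINS[spectrum.modality](spectrum)
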