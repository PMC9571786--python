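"""Continuous wavelet transform with generalized Morse wavelets,
synchrosqueezing, inversion, and rendering of scalograms to RGB images.

The transform implemented here is

    W(a, b) = (1/a) * integral s(t) * conj(psi((t - b)/a)) dt

evaluated per scale as a frequency-domain product: the L1-normalized scaled
wavelet has Fourier transform Psi(a * omega), so each scalogram row is
ifft(fft(s) * Psi(a * omega)).  The mother wavelet is the analytic
generalized Morse wavelet, Psi(omega) proportional to omega^beta *
exp(-omega^gamma) for omega > 0 and zero otherwise, peak-normalized to 2
(the usual analytic-wavelet convention, so that a real tone of unit
amplitude yields unit-magnitude ridge coefficients).

Synchrosqueezing reassigns each coefficient along the frequency axis to the
bin of its instantaneous frequency, Im[(dW/db) / W] / (2*pi); the
log-scale-weighted frequency marginal is preserved exactly, which is what
the one-integral inversion formula consumes, so both the plain and the
squeezed transforms are invertible here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.special import gammaln

__all__ = [
    "WaveletParams",
    "Scalogram",
    "RGBImage",
    "gmw_frequency_response",
    "cwt",
    "synchrosqueeze",
    "invert_cwt",
    "scalogram_to_rgb",
    "jet_colormap",
    "bilinear_resize",
    "save_png",
]


@dataclass(frozen=True)
class WaveletParams:
    """Generalized Morse wavelet and scale-grid parameters.

    gamma controls the wavelet symmetry, beta its time-bandwidth trade-off
    (defaults gamma=3, beta=60 are a common 'gmw' convention); nv is the
    number of voices per octave on the log scale grid.
    """

    gamma: float = 3.0
    beta: float = 60.0
    nv: int = 64
    scale_spacing: str = "log"
    scale_range: tuple | None = None

    def __post_init__(self):
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")
        if self.nv < 1:
            raise ValueError("nv must be >= 1")
        if self.scale_spacing != "log":
            raise ValueError("only log scale spacing is supported")

    @property
    def peak_omega(self) -> float:
        """Angular frequency of the wavelet's spectral peak, (beta/gamma)^(1/gamma)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    def scales_for(self, n: int) -> np.ndarray:
        """Log-spaced scales: peak frequency from ~Nyquist down to ~4 cycles/signal."""
        if self.scale_range is not None:
            a_min, a_max = self.scale_range
            if not 0 < a_min < a_max:
                raise ValueError("scale_range must satisfy 0 < a_min < a_max")
        else:
            a_min = self.peak_omega / np.pi
            a_max = self.peak_omega / (2.0 * np.pi * 2.0 / n)
        n_scales = int(np.floor(self.nv * np.log2(a_max / a_min))) + 1
        return a_min * 2.0 ** (np.arange(n_scales) / self.nv)

    def scale_to_frequency(self, scales) -> np.ndarray:
        """Peak frequency (cycles/sample) carried by each scale."""
        return self.peak_omega / (2.0 * np.pi * np.asarray(scales))

    def admissibility_constant(self) -> float:
        """C = integral_0^inf Psi(u)/u du for the peak-2-normalized wavelet."""
        g, b = self.gamma, self.beta
        wp = self.peak_omega
        log_k = np.log(2.0) - b * np.log(wp) + wp**g
        return float(np.exp(log_k + gammaln(b / g) - np.log(g)))


@dataclass
class Scalogram:
    """Time-frequency (or time-scale) coefficient matrix.

    ``axis`` records what the rows index: raw CWT rows are scales
    (ascending scale = descending frequency); synchrosqueezed rows are
    frequency bins in cycles/sample (ascending).
    """

    values: np.ndarray            # (n_rows, n_positions)
    scales: np.ndarray            # per-row scale or frequency axis
    positions: np.ndarray         # per-column axis, aligned to the input grid
    axis: str = "scale"           # "scale" | "frequency"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("scalogram values must be 2D")
        if v.shape[0] != len(self.scales) or v.shape[1] != len(self.positions):
            raise ValueError("values shape must match scales x positions")
        if not np.all(np.isfinite(np.abs(v))):
            raise ValueError("scalogram magnitudes must be finite")
        if self.axis not in ("scale", "frequency"):
            raise ValueError("axis must be 'scale' or 'frequency'")
        self.values = v

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class RGBImage:
    """Height x width x 3 image; rendered scalograms are 224 x 224 in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        self.pixels = p

    @property
    def shape(self):
        return self.pixels.shape


def _log_gmw(omega, gamma, beta):
    """log response at omega > 0 for the peak-2-normalized Morse wavelet."""
    wp = (beta / gamma) ** (1.0 / gamma)
    ref = beta * np.log(wp) - wp**gamma
    with np.errstate(divide="ignore"):
        return np.log(2.0) + beta * np.log(omega) - omega**gamma - ref


def gmw_frequency_response(params: WaveletParams, scale: float, n: int) -> np.ndarray:
    """Sample the analytic Morse filter Psi(a * omega_k) on a length-n fft grid.

    omega_k = 2*pi*k/n; entries at non-positive frequencies (k = 0 and
    k > n/2) are zero, making the filter one-sided (analytic).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    k = np.arange(n)
    omega = 2.0 * np.pi * k / n
    pos = (k >= 1) & (k <= n // 2)
    out = np.zeros(n)
    out[pos] = np.exp(_log_gmw(scale * omega[pos], params.gamma, params.beta))
    return out


def _pad_reflect(x: np.ndarray):
    """Reflect-pad to an fft-friendly length >= 2 * len(x)."""
    n = len(x)
    total = next_fast_len(2 * n)
    left = n // 2
    right = total - n - left
    cap = n - 1  # np.pad reflect limit
    lp, rp = min(left, cap), min(right, cap)
    xp = np.pad(x, (lp, rp), mode="reflect")
    if left - lp or right - rp:  # top up with edge values in the rare long-pad case
        xp = np.pad(xp, (left - lp, right - rp), mode="edge")
    return xp, left, total


def _transform(x, params, boundary, derivative=False):
    """Padded frequency-domain CWT; optionally also the d/db transform."""
    n = len(x)
    if boundary == "reflect":
        xp, offset, total = _pad_reflect(x)
    elif boundary == "periodic":
        xp, offset, total = x, 0, n
    else:
        raise ValueError("boundary must be 'reflect' or 'periodic'")
    scales = params.scales_for(n)
    X = fft(xp)
    k = np.arange(total)
    omega = 2.0 * np.pi * k / total
    pos = (k >= 1) & (k <= total // 2)
    psi = np.zeros((len(scales), total))
    arg = scales[:, None] * omega[None, pos]
    psi[:, pos] = np.exp(_log_gmw(arg, params.gamma, params.beta))
    W = ifft(psi * X[None, :], axis=1)[:, offset:offset + n]
    if not derivative:
        return W, scales
    dW = ifft(psi * (1j * omega * X)[None, :], axis=1)[:, offset:offset + n]
    return W, dW, scales


def cwt(signal, params: WaveletParams | None = None,
        boundary: str = "reflect", positions=None) -> Scalogram:
    """Continuous wavelet transform of a 1D signal.

    Rows are scales (log-spaced, ``nv`` voices per octave); columns align
    with the input samples.  ``boundary='reflect'`` suppresses wrap-around
    edge artifacts; ``'periodic'`` computes the exact circular transform.
    """
    params = WaveletParams() if params is None else params
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1D")
    if len(x) < 8:
        raise ValueError("signal must have at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    W, scales = _transform(x, params, boundary)
    pos = np.arange(len(x)) if positions is None else np.asarray(positions)
    return Scalogram(W, scales, pos, axis="scale")


def synchrosqueeze(scalogram: Scalogram, signal, params: WaveletParams | None = None,
                   boundary: str = "reflect") -> Scalogram:
    """Reassign CWT energy along the frequency axis via the phase transform.

    Each coefficient W(a, b) moves to the log-spaced frequency bin nearest
    its instantaneous frequency Im[(dW/db)/W]/(2*pi), weighted by d(log a),
    so that summing the output over bins reproduces the log-scale-weighted
    sum over scales (the quantity the inversion formula integrates).
    """
    params = WaveletParams() if params is None else params
    if not np.iscomplexobj(scalogram.values):
        raise ValueError("synchrosqueezing needs the complex transform, "
                         "not a magnitude scalogram")
    x = np.asarray(signal, dtype=float)
    W, dW, scales = _transform(x, params, boundary, derivative=True)
    if W.shape != scalogram.values.shape:
        raise ValueError("scalogram shape does not match signal/params")
    freqs = params.scale_to_frequency(scales)[::-1]  # ascending, cycles/sample
    n_bins = len(freqs)
    dloga = np.log(2.0) / params.nv
    with np.errstate(divide="ignore", invalid="ignore"):
        finst = np.imag(dW / W) / (2.0 * np.pi)
    valid = np.isfinite(finst) & (finst > 0) & (np.abs(W) > 0)
    # bins are log2-spaced at 1/nv: nearest bin by rounded log2 distance
    idx = np.round(np.log2(finst, where=valid, out=np.zeros_like(finst))
                   / (1.0 / params.nv) - params.nv * np.log2(freqs[0])).astype(int)
    valid &= (idx >= 0) & (idx < n_bins)
    rows, cols = np.nonzero(valid)
    out = np.zeros((n_bins, W.shape[1]), dtype=complex)
    np.add.at(out, (idx[rows, cols], cols), W[rows, cols] * dloga)
    return Scalogram(out, freqs, scalogram.positions, axis="frequency")


def _coverage(params: WaveletParams, n: int) -> np.ndarray:
    """C(omega_k) = sum_a Psi(a * omega_k) d(log a) on a length-n fft grid.

    Flat (equal to the admissibility constant) on the frequency band the
    scale grid covers, rolling off outside it.
    """
    scales = params.scales_for(n)
    k = np.arange(n)
    omega = 2.0 * np.pi * k / n
    pos = (k >= 1) & (k <= n // 2)
    arg = scales[:, None] * omega[None, pos]
    cov = np.zeros(n)
    cov[pos] = np.exp(_log_gmw(arg, params.gamma, params.beta)).sum(axis=0)
    return cov * (np.log(2.0) / params.nv)


def project_to_band(signal, params: WaveletParams | None = None,
                    rel_tol: float = 0.25) -> np.ndarray:
    """Project a signal onto the frequency band the scale grid covers.

    Keeps the Fourier components where the wavelet-frame coverage exceeds
    ``rel_tol`` of its maximum; the result is band-limited within the
    transform's scale range (the precondition for accurate inversion).
    """
    params = WaveletParams() if params is None else params
    x = np.asarray(signal, dtype=float)
    n = len(x)
    cov = _coverage(params, n)
    keep = cov >= rel_tol * cov.max()
    keep = keep | np.roll(keep[::-1], 1)  # hermitian partner of each kept bin
    X = fft(x)
    X[~keep] = 0.0
    return np.real(ifft(X))


def invert_cwt(scalogram: Scalogram, params: WaveletParams | None = None) -> np.ndarray:
    """Reconstruct the (zero-mean, band-limited part of the) signal.

    Scale-axis scalograms use the frame inversion: the d(log a)-weighted
    scale marginal m(b) has spectrum X(omega) * C(omega) with C the
    coverage function, so dividing by C on the covered band recovers the
    analytic signal, whose real part is x.  Frequency-axis (synchrosqueezed)
    scalograms use the classic one-integral formula, summing bins and
    scaling by 2/C with the scalar admissibility constant.

    Inversion is exact (to rounding) for transforms computed with
    ``boundary='periodic'``; reflect-padded transforms round-trip
    approximately, with the error concentrated near the signal edges.
    """
    params = WaveletParams() if params is None else params
    vals = scalogram.values
    n = vals.shape[1]
    if scalogram.axis == "scale":
        if len(params.scales_for(n)) != vals.shape[0]:
            raise ValueError("scalogram scale axis does not match params")
        marginal = vals.sum(axis=0) * (np.log(2.0) / params.nv)
        cov = _coverage(params, n)
        covered = cov >= 0.25 * cov.max()
        M = fft(marginal)
        Xhat = np.zeros_like(M)
        Xhat[covered] = M[covered] / cov[covered]
        return 2.0 * np.real(ifft(Xhat))
    if len(scalogram.scales) != vals.shape[0]:
        raise ValueError("scalogram frequency axis does not match values")
    integrand = vals.sum(axis=0)
    return np.real(integrand) * 2.0 / params.admissibility_constant()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def jet_colormap(v: np.ndarray) -> np.ndarray:
    """Classic piecewise-linear JET map (blue -> cyan -> yellow -> red).

    v in [0, 1]; v=0 renders dark blue (0, 0, 0.5) and v=1 dark red
    (0.5, 0, 0).  Defined in closed form so renders are identical across
    platforms.
    """
    v = np.asarray(v, dtype=float)
    r = np.clip(1.5 - np.abs(4.0 * v - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * v - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * v - 1.0), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize (pixel-center sampling), 2D or 2D+channels."""
    h, w = img.shape[:2]
    ys = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0).reshape(-1, 1)
    wx = (xs - x0).reshape(1, -1)
    if img.ndim == 3:
        wy = wy[..., None]
        wx = wx[..., None]
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return top * (1 - wy) + bot * wy


def scalogram_to_rgb(scalogram: Scalogram, out_size: int = 224) -> RGBImage:
    """Render a scalogram as a JET-colored RGB image.

    magnitude -> logarithmic compression log1p(K * m / max(m)) / log1p(K)
    with K = 1000 (tames the baseline-dominated dynamic range while staying
    invariant to positive rescaling of the magnitudes) -> per-image min-max
    to [0, 1] -> JET -> bilinear resize to ``out_size`` x ``out_size``.
    Rows are oriented high-frequency-up; a constant scalogram maps to the
    value-0 color everywhere.
    """
    mag = scalogram.magnitude()
    if not np.all(np.isfinite(mag)):
        raise ValueError("scalogram magnitudes must be finite")
    peak = mag.max()
    if peak == 0:
        g = np.zeros_like(mag)
    else:
        K = 1000.0
        g = np.log1p(K * mag / peak) / np.log1p(K)
    lo, hi = g.min(), g.max()
    g = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo)
    if scalogram.axis == "frequency":  # ascending frequency -> flip so high is on top
        g = g[::-1]
    rgb = jet_colormap(g)
    return RGBImage(np.clip(bilinear_resize(rgb, out_size, out_size), 0.0, 1.0))


def save_png(image: RGBImage, path) -> None:
    from PIL import Image

    arr = (np.clip(image.pixels, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr).save(path)
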