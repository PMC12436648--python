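"""Per-frame fluorescent spot detection and sub-pixel Gaussian fitting.

Diffraction-limited spots are enhanced with a scale-normalized Laplacian-of-
Gaussian band-pass, candidate pixels are local maxima above an amplitude
threshold, and each candidate is refined by least-squares fitting of a
pixel-integrated elliptical Gaussian with a free offset.  The integrated
spot intensity is the analytic volume of the fitted Gaussian,
``2*pi*amplitude*sigma_x*sigma_y`` (times ``sqrt(2*pi)*sigma_z`` in 3D).

Coordinates are 0-based with the pixel-center convention: the center of
pixel ``(i, j)`` is at ``(x=j, y=i)`` and the pixel spans ``+/- 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

__all__ = [
    "DetectionParams",
    "Spot",
    "bandpass_log",
    "robust_threshold",
    "find_candidates",
    "fit_gaussian",
    "detect_spots",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection settings.

    Parameters
    ----------
    log_sigma_px:
        Band-pass scale (pixels); should match the PSF standard deviation.
    min_amplitude:
        Candidate threshold in filtered-image units.  ``None`` selects an
        automatic threshold of ``threshold_k`` robust standard deviations
        of the filtered image.
    threshold_k:
        Multiple of the robust SD used when ``min_amplitude`` is ``None``.
    fit_half_px:
        Half-width of the square (cube) fitting window, so the window is
        ``2*fit_half_px + 1`` pixels on a side.
    dims:
        2 for time-lapse planes, 3 for z-stacks.
    """

    log_sigma_px: float = 1.3
    min_amplitude: Optional[float] = None
    threshold_k: float = 3.0
    fit_half_px: int = 4
    dims: int = 2
    # when > 0, fitted spots with amplitude below this multiple of the
    # raw image's robust noise SD are rejected (guards against noise
    # maxima that slip past the candidate threshold)
    amp_threshold_k: float = 0.0
    # accepted fitted-width range relative to log_sigma_px; fits far from
    # the PSF width are noise or merged spots
    width_band: tuple[float, float] = (0.6, 2.0)

    def __post_init__(self) -> None:
        if self.log_sigma_px <= 0:
            raise ValueError("log_sigma_px must be > 0")
        if self.min_amplitude is not None and self.min_amplitude <= 0:
            raise ValueError("min_amplitude must be > 0")
        if self.fit_half_px < 2 * self.log_sigma_px:
            raise ValueError("fit window must cover at least 2 x log_sigma_px")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")


@dataclass
class Spot:
    """One sub-pixel detection."""

    frame: int
    x: float
    y: float
    amplitude: float
    sigma_x: float
    sigma_y: float
    background: float
    integrated_intensity: float
    z: Optional[float] = None
    sigma_z: Optional[float] = None
    channel: str = ""
    edge: bool = False

    @property
    def position(self) -> np.ndarray:
        if self.z is None:
            return np.array([self.x, self.y])
        return np.array([self.x, self.y, self.z])


def bandpass_log(image: np.ndarray, log_sigma_px: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian band-pass.

    Returns ``-sigma^2 * LoG(image)`` so that Gaussian blobs of width
    ``log_sigma_px`` respond with a positive maximum at the blob center.
    Linear in the input; a constant image maps to (numerically) zero.
    """
    if log_sigma_px <= 0:
        raise ValueError("log_sigma_px must be > 0")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return -(log_sigma_px**2) * ndimage.gaussian_laplace(image, log_sigma_px)


def robust_threshold(filtered: np.ndarray, k: float = 3.0) -> float:
    """``k`` times the robust (MAD-based) SD of a filtered image."""
    med = np.median(filtered)
    mad = np.median(np.abs(filtered - med))
    return float(k * 1.4826 * mad)


def find_candidates(filtered: np.ndarray, min_amplitude: float,
                    min_distance: int = 3) -> np.ndarray:
    """Local maxima of the band-passed image above ``min_amplitude``.

    No two candidates lie within ``min_distance`` pixels of each other;
    the brighter one wins.  Returns an ``(n, ndim)`` integer array of
    pixel indices (row-major order, i.e. ``(y, x)`` or ``(z, y, x)``).
    """
    if min_amplitude <= 0:
        raise ValueError("min_amplitude must be > 0")
    coords = peak_local_max(
        np.asarray(filtered, dtype=float),
        min_distance=max(1, int(min_distance)),
        threshold_abs=float(min_amplitude),
        exclude_border=False,
    )
    # deterministic order: sort by index tuple
    if len(coords):
        order = np.lexsort(coords.T[::-1])
        coords = coords[order]
    return coords


def _pixel_profile(coords: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit-area 1D Gaussian over unit pixels centered at coords."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((coords + 0.5 - mu) / s) - erf((coords - 0.5 - mu) / s))


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _profile_grads(coords: np.ndarray, mu: float,
                   sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(profile, d/dmu, d/dsigma) of the unit-pixel Gaussian integral."""
    a = (coords + 0.5 - mu) / sigma
    b = (coords - 0.5 - mu) / sigma
    pa = np.exp(-0.5 * a * a) / _SQRT2PI
    pb = np.exp(-0.5 * b * b) / _SQRT2PI
    p = 0.5 * (erf(a / np.sqrt(2.0)) - erf(b / np.sqrt(2.0)))
    return p, -(pa - pb) / sigma, -(a * pa - b * pb) / sigma


def _model_2d(params, yy, xx):
    x0, y0, sx, sy, amp, bg = params
    px = _pixel_profile(xx, x0, sx)
    py = _pixel_profile(yy, y0, sy)
    return bg + amp * 2.0 * np.pi * sx * sy * np.outer(py, px)


def _jac_2d(params, yy, xx):
    x0, y0, sx, sy, amp, bg = params
    px, dpx_mu, dpx_s = _profile_grads(xx, x0, sx)
    py, dpy_mu, dpy_s = _profile_grads(yy, y0, sy)
    c = 2.0 * np.pi
    pxy = np.outer(py, px)
    n = pxy.size
    J = np.empty((n, 6))
    J[:, 0] = (c * amp * sx * sy * np.outer(py, dpx_mu)).ravel()
    J[:, 1] = (c * amp * sx * sy * np.outer(dpy_mu, px)).ravel()
    J[:, 2] = (c * amp * sy * np.outer(py, px + sx * dpx_s)).ravel()
    J[:, 3] = (c * amp * sx * np.outer(py + sy * dpy_s, px)).ravel()
    J[:, 4] = (c * sx * sy * pxy).ravel()
    J[:, 5] = 1.0
    return J


def _jac_3d(params, zz, yy, xx):
    x0, y0, z0, sx, sy, sz, amp, bg = params
    px, dpx_mu, dpx_s = _profile_grads(xx, x0, sx)
    py, dpy_mu, dpy_s = _profile_grads(yy, y0, sy)
    pz, dpz_mu, dpz_s = _profile_grads(zz, z0, sz)
    c = (2.0 * np.pi) ** 1.5

    def triple(a, b, d):
        return (a[:, None, None] * b[None, :, None]
                * d[None, None, :]).ravel()

    n = len(zz) * len(yy) * len(xx)
    J = np.empty((n, 8))
    J[:, 0] = c * amp * sx * sy * sz * triple(pz, py, dpx_mu)
    J[:, 1] = c * amp * sx * sy * sz * triple(pz, dpy_mu, px)
    J[:, 2] = c * amp * sx * sy * sz * triple(dpz_mu, py, px)
    J[:, 3] = c * amp * sy * sz * triple(pz, py, px + sx * dpx_s)
    J[:, 4] = c * amp * sx * sz * triple(pz, py + sy * dpy_s, px)
    J[:, 5] = c * amp * sx * sy * triple(pz + sz * dpz_s, py, px)
    J[:, 6] = c * sx * sy * sz * triple(pz, py, px)
    J[:, 7] = 1.0
    return J


def _model_3d(params, zz, yy, xx):
    x0, y0, z0, sx, sy, sz, amp, bg = params
    px = _pixel_profile(xx, x0, sx)
    py = _pixel_profile(yy, y0, sy)
    pz = _pixel_profile(zz, z0, sz)
    vol = amp * (2.0 * np.pi) ** 1.5 * sx * sy * sz
    return bg + vol * pz[:, None, None] * py[None, :, None] * px[None, None, :]


def fit_gaussian(image: np.ndarray, candidate: Sequence[int],
                 params: DetectionParams, frame: int = 0,
                 channel: str = "") -> tuple[Optional[Spot], Optional[str]]:
    """Least-squares fit of offset + pixel-integrated elliptical Gaussian.

    ``candidate`` is an integer pixel index in row-major order.  The fit
    window is shrunk (and the spot flagged ``edge``) when the candidate
    sits near the image border.  Returns ``(spot, None)`` on success or
    ``(None, reason)`` on rejection.
    """
    image = np.asarray(image, dtype=float)
    ndim = image.ndim
    if ndim != params.dims:
        raise ValueError(f"image is {ndim}D but params.dims={params.dims}")
    h = int(params.fit_half_px)
    cand = tuple(int(c) for c in candidate)
    lo = [max(0, c - h) for c in cand]
    hi = [min(n, c + h + 1) for c, n in zip(cand, image.shape)]
    edge = any(l != c - h or u != c + h + 1
               for l, u, c in zip(lo, hi, cand))
    # lateral window must stay usable
    if any(u - l < 3 for l, u in zip(lo[-2:], hi[-2:])):
        return None, "window_too_small"
    window = image[tuple(slice(l, u) for l, u in zip(lo, hi))]
    if np.ptp(window) == 0:
        return None, "no_signal"

    bg0 = float(np.min(window))
    amp0 = float(window[tuple(c - l for c, l in zip(cand, lo))] - bg0)
    if amp0 <= 0:
        return None, "no_signal"
    sig0 = params.log_sigma_px

    if ndim == 2:
        yy = np.arange(lo[0], hi[0], dtype=float)
        xx = np.arange(lo[1], hi[1], dtype=float)
        p0 = [cand[1], cand[0], sig0, sig0, amp0, bg0]

        def resid(p):
            return (_model_2d(p, yy, xx) - window).ravel()

        def jac(p):
            return _jac_2d(p, yy, xx)
    else:
        zz = np.arange(lo[0], hi[0], dtype=float)
        yy = np.arange(lo[1], hi[1], dtype=float)
        xx = np.arange(lo[2], hi[2], dtype=float)
        p0 = [cand[2], cand[1], cand[0], sig0, sig0, sig0, amp0, bg0]

        def resid(p):
            return (_model_3d(p, zz, yy, xx) - window).ravel()

        def jac(p):
            return _jac_3d(p, zz, yy, xx)

    try:
        res = least_squares(resid, p0, jac=jac, method="lm", xtol=1e-10,
                            max_nfev=300)
    except Exception:
        return None, "fit_error"
    if not res.success:
        return None, "no_convergence"

    if ndim == 2:
        x0, y0, sx, sy, amp, bg = res.x
        z0 = sz = None
        sigmas = (sx, sy) = abs(sx), abs(sy)
        integ = 2.0 * np.pi * amp * sx * sy
        centers = (x0, y0)
        axes_lo = (lo[1], lo[0])
        axes_hi = (hi[1], hi[0])
    else:
        x0, y0, z0, sx, sy, sz, amp, bg = res.x
        sigmas = (sx, sy, sz) = abs(sx), abs(sy), abs(sz)
        integ = (2.0 * np.pi) ** 1.5 * amp * sx * sy * sz
        centers = (x0, y0, z0)
        axes_lo = (lo[2], lo[1], lo[0])
        axes_hi = (hi[2], hi[1], hi[0])
    if amp <= 0:
        return None, "negative_amplitude"
    if any(c < a - 1.0 or c > b for c, a, b in zip(centers, axes_lo,
                                                   axes_hi)):
        return None, "diverged"
    wlo, whi = params.width_band
    if any(s < wlo * params.log_sigma_px or s > whi * params.log_sigma_px
           or s > 4.0 * h for s in sigmas):
        return None, "bad_width"

    spot = Spot(frame=frame, x=float(x0), y=float(y0),
                z=None if z0 is None else float(z0),
                amplitude=float(amp), sigma_x=float(sx), sigma_y=float(sy),
                sigma_z=None if sz is None else float(sz),
                background=float(bg), integrated_intensity=float(integ),
                channel=channel, edge=edge)
    return spot, None


def detect_spots(stack: np.ndarray, params: DetectionParams,
                 channel: str = "") -> list[list[Spot]]:
    """Detect and fit spots in every frame of a time-lapse stack.

    ``stack`` has shape ``(t, y, x)`` for 2D detection or ``(z, y, x)``
    for a single 3D volume (``params.dims == 3``, returns one frame).
    Deterministic given inputs; rejected fits are silently dropped.
    """
    stack = np.asarray(stack, dtype=float)
    if params.dims == 3:
        frames = [stack]
    else:
        if stack.ndim == 2:
            frames = [stack]
        else:
            frames = list(stack)
    out: list[list[Spot]] = []
    min_dist = max(1, int(round(2 * params.log_sigma_px)))
    for t, frame_img in enumerate(frames):
        filt = bandpass_log(frame_img, params.log_sigma_px)
        thr = params.min_amplitude
        if thr is None:
            thr = robust_threshold(filt, params.threshold_k)
            thr = max(thr, 1e-12)
        cands = find_candidates(filt, thr, min_distance=min_dist)
        amp_gate = 0.0
        if params.amp_threshold_k > 0:
            med = np.median(frame_img)
            noise_sd = 1.4826 * np.median(np.abs(frame_img - med))
            amp_gate = params.amp_threshold_k * noise_sd
        spots = []
        for cand in cands:
            spot, _ = fit_gaussian(frame_img, cand, params, frame=t,
                                   channel=channel)
            if spot is not None and spot.amplitude >= amp_gate:
                spots.append(spot)
        out.append(spots)
    return out
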