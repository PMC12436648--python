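"""Rendering of synthetic microscopy images.

Point emitters are rendered through a pixel-integrated Gaussian PSF
(separable in z for 3D volumes), so the total expected photon count of a
spot equals ``intensity * photons_per_unit`` independent of its sub-pixel
position.  Pixel noise is Poisson shot noise on the expected photon image
plus additive Gaussian read noise, the standard sCMOS/EMCCD approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import erf

__all__ = ["RenderConfig", "ImageStack", "render_frame", "render_movie"]


@dataclass(frozen=True)
class RenderConfig:
    """Imaging-model calibration for rendered synthetic data.

    Defaults mirror a TIRF acquisition at 160 nm pixels and 2-s frames
    (10-s frames are typical for runoff imaging and are set per run).
    The photon budget is a declared simulation parameter, not a fitted
    quantity.
    """

    pixel_size_nm: float = 160.0
    frame_interval_s: float = 2.0
    n_frames: int = 150
    field_px: int = 128
    psf_sigma_px: float = 1.3
    psf_sigma_z_px: float = 1.0
    photons_per_unit: float = 2000.0
    background_mean: float = 100.0
    read_noise_sd: float = 2.0
    diffusion_coeff_um2_s: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "frame_interval_s", "n_frames",
                     "field_px", "psf_sigma_px", "photons_per_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.psf_sigma_px < 0.5:
            raise ValueError("psf_sigma_px must be >= 0.5 (Nyquist sampling)")
        if self.background_mean < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageStack:
    """A channel's pixel array plus spatial/temporal calibration."""

    data: np.ndarray            # (t, y, x) or (z, y, x)
    pixel_size_nm: float
    frame_interval_s: float
    channel: str = ""
    z_step_nm: float | None = None


def _profile(n: int, lo: int, mu: float, sigma: float) -> np.ndarray:
    coords = np.arange(lo, lo + n, dtype=float)
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((coords + 0.5 - mu) / s) - erf((coords - 0.5 - mu) / s))


def add_spot_2d(expected: np.ndarray, x: float, y: float, photons: float,
                sigma: float) -> None:
    """Stamp an integrated-Gaussian spot (in place) on an expected-photon image."""
    ny, nx = expected.shape
    r = int(np.ceil(5 * sigma)) + 1
    x0, x1 = max(0, int(np.floor(x)) - r), min(nx, int(np.ceil(x)) + r + 1)
    y0, y1 = max(0, int(np.floor(y)) - r), min(ny, int(np.ceil(y)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    px = _profile(x1 - x0, x0, x, sigma)
    py = _profile(y1 - y0, y0, y, sigma)
    expected[y0:y1, x0:x1] += photons * np.outer(py, px)


def add_spot_3d(expected: np.ndarray, x: float, y: float, z: float,
                photons: float, sigma_xy: float, sigma_z: float) -> None:
    nz, ny, nx = expected.shape
    r = int(np.ceil(5 * sigma_xy)) + 1
    rz = int(np.ceil(5 * sigma_z)) + 1
    x0, x1 = max(0, int(np.floor(x)) - r), min(nx, int(np.ceil(x)) + r + 1)
    y0, y1 = max(0, int(np.floor(y)) - r), min(ny, int(np.ceil(y)) + r + 1)
    z0, z1 = max(0, int(np.floor(z)) - rz), min(nz, int(np.ceil(z)) + rz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    px = _profile(x1 - x0, x0, x, sigma_xy)
    py = _profile(y1 - y0, y0, y, sigma_xy)
    pz = _profile(z1 - z0, z0, z, sigma_z)
    expected[z0:z1, y0:y1, x0:x1] += (
        photons * pz[:, None, None] * py[None, :, None] * px[None, None, :]
    )


def apply_noise(expected: np.ndarray, cfg: RenderConfig,
                rng: np.random.Generator) -> np.ndarray:
    img = rng.poisson(expected).astype(float)
    if cfg.read_noise_sd > 0:
        img += rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return img


def render_frame(positions: np.ndarray, intensities: np.ndarray,
                 cfg: RenderConfig, rng: np.random.Generator | None = None,
                 noiseless: bool = False) -> np.ndarray:
    """Render one 2D frame from ``(n, 2)`` x/y positions and unit intensities.

    With ``noiseless=True`` the expected photon image (background included)
    is returned without sampling.
    """
    n = cfg.field_px
    expected = np.full((n, n), float(cfg.background_mean))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    for (x, y), inten in zip(positions, np.atleast_1d(intensities)):
        if inten <= 0:
            continue
        if not (0 <= x < n and 0 <= y < n):
            raise ValueError(f"emitter at ({x:.1f}, {y:.1f}) outside field")
        add_spot_2d(expected, x, y, inten * cfg.photons_per_unit,
                    cfg.psf_sigma_px)
    if noiseless:
        return expected
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return apply_noise(expected, cfg, rng)


def render_movie(positions: np.ndarray, intensities: np.ndarray,
                 cfg: RenderConfig, channel: str = "",
                 noiseless: bool = False,
                 seed: int | None = None) -> ImageStack:
    """Render a time-lapse channel.

    Parameters
    ----------
    positions:
        ``(n_molecules, n_frames, 2)`` x/y trajectories in pixels.
    intensities:
        ``(n_molecules, n_frames)`` per-frame intensities in calibration
        units (a single fluorescent binder = 1).  Frames where a molecule
        is dark carry intensity <= 0 and contribute nothing.

    Identical ``(positions, intensities, cfg, seed)`` give a bit-identical
    stack.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if positions.ndim != 3 or positions.shape[2] != 2:
        raise ValueError("positions must have shape (n_molecules, n_frames, 2)")
    n_mol, n_frames = intensities.shape
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = np.empty((n_frames, cfg.field_px, cfg.field_px))
    for t in range(n_frames):
        frames[t] = render_frame(positions[:, t, :], intensities[:, t], cfg,
                                 rng=rng, noiseless=noiseless)
    return ImageStack(data=frames, pixel_size_nm=cfg.pixel_size_nm,
                      frame_interval_s=cfg.frame_interval_s, channel=channel)
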