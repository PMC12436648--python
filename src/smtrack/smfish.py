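"""Nascent-peptide quantification from fixed-cell smFISH-IF fields.

mRNA spots are detected in the FISH channel (LoG band-pass, 3D Gaussian
fitting) inside per-cell masks.  Protein-channel spots within a maximal
distance of an mRNA spot are translation sites; the remaining protein
spots, outside all translation-site regions of interest, are mature
single proteins.  The nascent-peptide (NAP) count of a translation site
is its integrated intensity divided by the mean single-protein intensity
of the same cell, which makes the count invariant to global intensity
rescaling of the protein channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detection import DetectionParams, Spot, detect_spots
from .render import ImageStack

__all__ = ["FishField", "TranslationSite", "detect_mrna_spots",
           "detect_translation_sites", "single_protein_intensity",
           "nap_counts", "compare_nap_distributions"]


@dataclass
class FishField:
    """One two-channel 3D field with a per-cell label mask."""

    mrna: ImageStack
    protein: ImageStack
    mask: np.ndarray            # 2D integer label image (0 = background)

    def __post_init__(self) -> None:
        if self.mrna.data.shape != self.protein.data.shape:
            raise ValueError("channel stacks must be congruent")
        if self.mask.shape != self.mrna.data.shape[-2:]:
            raise ValueError("mask must match the lateral stack shape")


@dataclass
class TranslationSite:
    cell_id: int
    x: float
    y: float
    z: float
    integrated_intensity: float
    sigma_x: float
    sigma_y: float
    sigma_z: float
    mrna_index: int
    distance_px: float
    nap_count: float = float("nan")


def _cell_of(mask: np.ndarray, spot: Spot) -> int:
    iy = int(np.clip(round(spot.y), 0, mask.shape[0] - 1))
    ix = int(np.clip(round(spot.x), 0, mask.shape[1] - 1))
    return int(mask[iy, ix])


def detect_mrna_spots(field: FishField,
                      params: DetectionParams | None = None) -> list[Spot]:
    """3D detection of mRNA spots, restricted to the cell masks."""
    params = params or DetectionParams(dims=3, threshold_k=4.0,
                                       amp_threshold_k=3.0,
                                       width_band=(0.5, 2.0))
    spots = detect_spots(field.mrna.data, params, channel="mrna")[0]
    return [s for s in spots if _cell_of(field.mask, s) > 0]


def detect_translation_sites(field: FishField, mrna_spots: list[Spot],
                             params: DetectionParams | None = None,
                             max_dist_px: float = 2.0,
                             max_dz_planes: float = 1.0,
                             min_amplitude: float | None = None
                             ) -> list[TranslationSite]:
    """Protein-channel 3D fits near an mRNA spot, linked to the nearest one.

    A candidate must lie within ``max_dist_px`` laterally and
    ``max_dz_planes`` axially of some mRNA spot and clear the amplitude
    threshold.
    """
    params = params or DetectionParams(dims=3, threshold_k=4.0,
                                       amp_threshold_k=3.0,
                                       width_band=(0.5, 2.0),
                                       min_amplitude=min_amplitude)
    prot = detect_spots(field.protein.data, params, channel="protein")[0]
    if not mrna_spots:
        return []
    mx = np.array([[m.x, m.y, m.z] for m in mrna_spots])
    out = []
    for s in prot:
        if min_amplitude is not None and s.amplitude < min_amplitude:
            continue
        lat = np.hypot(mx[:, 0] - s.x, mx[:, 1] - s.y)
        dz = np.abs(mx[:, 2] - s.z)
        ok = (lat <= max_dist_px) & (dz <= max_dz_planes)
        if not np.any(ok):
            continue
        cand = np.where(ok, lat, np.inf)
        j = int(np.argmin(cand))
        cell = _cell_of(field.mask, s)
        if cell <= 0:
            continue
        out.append(TranslationSite(
            cell_id=cell, x=s.x, y=s.y, z=s.z,
            integrated_intensity=s.integrated_intensity,
            sigma_x=s.sigma_x, sigma_y=s.sigma_y, sigma_z=s.sigma_z,
            mrna_index=j, distance_px=float(lat[j])))
    return out


def single_protein_intensity(field: FishField,
                             tls_list: list[TranslationSite],
                             params: DetectionParams | None = None,
                             roi_sigma_factor: float = 3.0,
                             min_n: int = 5
                             ) -> tuple[dict[int, float], dict[int, int],
                                        list[int]]:
    """Per-cell mean integrated intensity of mature single proteins.

    Protein spots inside any translation-site ROI (an ellipsoid of
    ``roi_sigma_factor`` fitted sigmas) are excluded.  Cells with fewer
    than ``min_n`` single-protein detections are dropped and reported.
    Returns ``(unit_mean_per_cell, n_per_cell, dropped_cells)``.
    """
    params = params or DetectionParams(dims=3, threshold_k=4.0,
                                       amp_threshold_k=3.0,
                                       width_band=(0.5, 2.0))
    prot = detect_spots(field.protein.data, params, channel="protein")[0]
    singles: dict[int, list[float]] = {}
    for s in prot:
        cell = _cell_of(field.mask, s)
        if cell <= 0:
            continue
        in_roi = False
        for t in tls_list:
            dx = (s.x - t.x) / (roi_sigma_factor * t.sigma_x)
            dy = (s.y - t.y) / (roi_sigma_factor * t.sigma_y)
            dz = (s.z - t.z) / (roi_sigma_factor * t.sigma_z)
            if dx * dx + dy * dy + dz * dz <= 1.0:
                in_roi = True
                break
        if not in_roi:
            singles.setdefault(cell, []).append(s.integrated_intensity)
    unit_means, counts, dropped = {}, {}, []
    for cell, vals in sorted(singles.items()):
        counts[cell] = len(vals)
        if len(vals) >= min_n:
            unit_means[cell] = float(np.mean(vals))
        else:
            dropped.append(cell)
    return unit_means, counts, dropped


def nap_counts(tls_list: list[TranslationSite],
               unit_means: dict[int, float]
               ) -> tuple[list[TranslationSite], list[TranslationSite]]:
    """Normalize each translation site by its own cell's unit intensity.

    A cell's unit mean is never applied to another cell; sites in cells
    without a defined unit intensity are returned separately as skipped.
    """
    quantified, skipped = [], []
    for t in tls_list:
        unit = unit_means.get(t.cell_id)
        if unit is None or unit <= 0:
            skipped.append(t)
            continue
        t.nap_count = t.integrated_intensity / unit
        quantified.append(t)
    return quantified, skipped


def compare_nap_distributions(a, b) -> tuple[float, float]:
    """Two-tailed t test on square-root-transformed NAP distributions.

    The square-root transform reduces the right skew of per-site counts
    before the (equal-variance) t test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("NAP counts must be >= 0")
    res = stats.ttest_ind(np.sqrt(a), np.sqrt(b), equal_var=True)
    return float(res.statistic), float(res.pvalue)
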