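"""Ground-truthed synthetic cohorts emulating the live-cell and smFISH assays.

Three generators cover the imaging experiments the pipeline analyzes:

- :func:`simulate_binding_cohort` — membrane-tethered mRNAs with stochastic
  protein binding (steady-state two/three-color imaging);
- :func:`simulate_runoff_cohort` — translation-site intensity decay after a
  translation-initiation block, with an optional runoff-resistant (damaged)
  subpopulation;
- :func:`simulate_smfish_field` — fixed-cell 3D two-channel fields with
  unit-intensity single proteins and k-fold brighter translation sites.

All generators are bit-reproducible for identical (preset, config, seed):
every molecule draws from its own child stream of a single SeedSequence.
Tethered-mRNA motion is confined diffusion in a harmonic well, modeled as
an Ornstein-Uhlenbeck process around a fixed anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .presets import (KineticPreset, RunoffPreset, NAP_PRESETS)
from .render import RenderConfig, ImageStack, add_spot_3d, apply_noise
from .detection import Spot
from .tracking import Track

__all__ = [
    "Episode", "MoleculeTruth", "GroundTruth", "BindingCohort",
    "RunoffCohort", "FishTruth",
    "simulate_binding_cohort", "simulate_runoff_cohort",
    "simulate_smfish_field", "draw_nap_counts", "cohort_to_tracks",
]


@dataclass
class Episode:
    """One binding episode of a (possibly unlabeled) binder on one site."""

    mrna_id: int
    site: int
    t_start: float
    t_end: float            # clipped to the observation window
    duration_s: float       # drawn duration (unclipped)
    labeled: bool = True
    censored_end: bool = False


@dataclass
class MoleculeTruth:
    mrna_id: int
    anchor: np.ndarray
    translating: bool = True
    engaged: bool = False
    damaged: bool = False
    znf_bound: bool = False
    clearance_time_s: float = float("nan")
    clearance_censored: bool = False
    nap_count: float = float("nan")


@dataclass
class GroundTruth:
    molecules: list[MoleculeTruth] = field(default_factory=list)
    episodes: list[Episode] = field(default_factory=list)
    window_s: float = 0.0
    dt_s: float = 0.0

    def episodes_for(self, mrna_id: int) -> list[Episode]:
        return [e for e in self.episodes if e.mrna_id == mrna_id]


@dataclass
class BindingCohort:
    preset: KineticPreset
    window_s: float
    dt_s: float
    times: np.ndarray                 # (n_frames,)
    positions: np.ndarray             # (n_mrna, n_frames, 2) pixels
    mrna_traces: np.ndarray           # (n_mrna, n_frames)
    protein_traces: np.ndarray
    tls_traces: np.ndarray
    truth: GroundTruth

    @property
    def n_mrna(self) -> int:
        return len(self.truth.molecules)


@dataclass
class RunoffCohort:
    preset: RunoffPreset
    window_s: float
    dt_s: float
    times: np.ndarray
    positions: np.ndarray
    mrna_traces: np.ndarray
    tls_traces: np.ndarray
    protein_traces: np.ndarray
    truth: GroundTruth


@dataclass
class FishTruth:
    mrna_xyz: np.ndarray              # (n_mrna, 3) x, y, z in pixels
    tls_xyz: np.ndarray               # (n_tls, 3)
    tls_mrna_index: np.ndarray        # (n_tls,) index into mrna_xyz
    single_xyz: np.ndarray            # (n_single, 3)
    nap_counts: np.ndarray
    degenerate: bool = False          # no single proteins: unit undefined


def _validate_window(n_mrna: int, window_s: float, dt_s: float) -> None:
    if n_mrna < 0:
        raise ValueError("n_mrna must be >= 0")
    if dt_s <= 0 or window_s < dt_s:
        raise ValueError("require window_s >= dt_s > 0")


def _place_anchors(n: int, field_px: float, min_sep_px: float,
                   rng: np.random.Generator, margin: float = 8.0,
                   max_tries: int = 20000) -> np.ndarray:
    anchors = []
    tries = 0
    while len(anchors) < n:
        cand = rng.uniform(margin, field_px - margin, size=2)
        if all(np.hypot(*(cand - a)) >= min_sep_px for a in anchors):
            anchors.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError("field too small to place molecules "
                             "without overlap")
    return np.array(anchors).reshape(n, 2)


def _ou_trajectory(anchor: np.ndarray, n_frames: int, dt_s: float,
                   rng: np.random.Generator, conf_sigma_px: float = 0.6,
                   relax_s: float = 10.0) -> np.ndarray:
    """Confined (harmonic-well) 2D wander around a fixed anchor."""
    rho = np.exp(-dt_s / relax_s)
    step_sd = conf_sigma_px * np.sqrt(1.0 - rho**2)
    pos = np.empty((n_frames, 2))
    x = anchor + rng.normal(0.0, conf_sigma_px, size=2)
    for k in range(n_frames):
        pos[k] = x
        x = anchor + rho * (x - anchor) + rng.normal(0.0, step_sd, size=2)
    return pos


def _renewal_episodes(preset: KineticPreset, mrna_id: int, window_s: float,
                      rng: np.random.Generator) -> list[Episode]:
    episodes = []
    for site in range(preset.n_sites):
        t = 0.0
        first = True
        while True:
            if first and preset.ensure_qualifying and site == 0:
                # engagement presets: an engaged mRNA shows one
                # qualifying-length event inside the window by definition
                margin = preset.min_qualify_s + 8.0
                t_on = rng.uniform(0.0, max(window_s - margin, 1.0))
            else:
                t_on = t + rng.exponential(1.0 / preset.duty_or_kon)
            if t_on >= window_s:
                break
            d = rng.exponential(preset.mean_on_s)
            if first and preset.ensure_qualifying and site == 0:
                d += preset.min_qualify_s
            first = False
            t_end = min(t_on + d, window_s)
            episodes.append(Episode(
                mrna_id=mrna_id, site=site, t_start=t_on, t_end=t_end,
                duration_s=d, labeled=bool(rng.random() < preset.label_eff),
                censored_end=t_on + d > window_s))
            t = t_on + d
    return episodes


def _mixture_episode(preset: KineticPreset, mrna_id: int, window_s: float,
                     rng: np.random.Generator, margin_s: float = 0.0,
                     beta_conc: float = 4.0) -> Episode:
    if rng.random() < preset.persistent_frac:
        t0 = rng.uniform(0.0, 0.5 * window_s)
        return Episode(mrna_id=mrna_id, site=0, t_start=t0, t_end=window_s,
                       duration_s=np.inf,
                       labeled=bool(rng.random() < preset.label_eff),
                       censored_end=True)
    mean_frac = preset.transient_mean_min * 60.0 / window_s
    if not 0.0 < mean_frac < 1.0:
        raise ValueError("transient_mean_min must lie inside the window")
    a = mean_frac * beta_conc
    b = (1.0 - mean_frac) * beta_conc
    d = window_s * rng.beta(a, b)
    # transient recruitments are by definition fully observed inside the
    # window: keep them clear of the first/last frame where possible
    hi = max(window_s - d - margin_s, margin_s + 1e-9)
    t0 = rng.uniform(min(margin_s, hi), hi)
    return Episode(mrna_id=mrna_id, site=0, t_start=t0, t_end=t0 + d,
                   duration_s=d,
                   labeled=bool(rng.random() < preset.label_eff),
                   censored_end=False)


def simulate_binding_cohort(preset: KineticPreset, n_mrna: int,
                            window_s: float = 300.0, dt_s: float = 2.0,
                            seed: int = 0, frac_translating: float = 1.0,
                            noise_sd: float = 0.1, tls_level: float = 5.0,
                            field_px: float = 256.0,
                            min_sep_px: float = 10.0) -> BindingCohort:
    """Simulate trace-level observations of one cell (field) of mRNAs.

    Each mRNA carries a constant-plateau mRNA trace; the protein trace is
    the number of concurrently bound, fluorescently labeled binders
    sampled at the frame instants, plus Gaussian noise; translating mRNAs
    additionally carry a translation-site plateau.  For ``episode_mixture``
    presets only translating mRNAs can be engaged (the protein binds
    ribosomes, not bare mRNA).
    """
    _validate_window(n_mrna, window_s, dt_s)
    n_frames = int(round(window_s / dt_s))
    times = np.arange(n_frames) * dt_s
    ss = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(ss.spawn(1)[0])
    mol_seeds = ss.spawn(n_mrna + 1)[1:] if n_mrna else []

    # a large pooled cohort needs a proportionally larger field
    field_px = max(field_px, np.ceil(np.sqrt(n_mrna) * 1.8 * min_sep_px) + 16)
    anchors = (_place_anchors(n_mrna, field_px, min_sep_px, place_rng)
               if n_mrna else np.zeros((0, 2)))
    truth = GroundTruth(window_s=window_s, dt_s=dt_s)
    positions = np.zeros((n_mrna, n_frames, 2))
    mrna_traces = np.zeros((n_mrna, n_frames))
    protein_traces = np.zeros((n_mrna, n_frames))
    tls_traces = np.zeros((n_mrna, n_frames))

    for i in range(n_mrna):
        rng = np.random.default_rng(mol_seeds[i])
        translating = bool(rng.random() < frac_translating)
        mixture = preset.dwell_model == "episode_mixture"
        can_engage = translating or not mixture
        engaged = bool(can_engage and preset.n_sites > 0
                       and rng.random() < preset.p_engaged)
        episodes: list[Episode] = []
        if engaged:
            if mixture:
                episodes = [_mixture_episode(preset, i, window_s, rng,
                                             margin_s=dt_s)]
            else:
                episodes = _renewal_episodes(preset, i, window_s, rng)
        occupancy = np.zeros(n_frames)
        for ep in episodes:
            if ep.labeled:
                occupancy += ((times >= ep.t_start) & (times < ep.t_end))
        positions[i] = _ou_trajectory(anchors[i], n_frames, dt_s, rng)
        mrna_traces[i] = 1.0 + rng.normal(0.0, noise_sd, n_frames)
        protein_traces[i] = occupancy + rng.normal(0.0, noise_sd, n_frames)
        tls_traces[i] = (tls_level if translating else 0.0) \
            + rng.normal(0.0, noise_sd, n_frames)
        truth.molecules.append(MoleculeTruth(
            mrna_id=i, anchor=anchors[i], translating=translating,
            engaged=engaged))
        truth.episodes.extend(episodes)

    return BindingCohort(preset=preset, window_s=window_s, dt_s=dt_s,
                         times=times, positions=positions,
                         mrna_traces=mrna_traces,
                         protein_traces=protein_traces,
                         tls_traces=tls_traces, truth=truth)


def _draw_clearance(baseline: dict, rng: np.random.Generator) -> float:
    dist = baseline.get("dist", "lognormal")
    if dist != "lognormal":
        raise ValueError(f"unsupported baseline distribution {dist!r}")
    median = float(baseline["median_s"])
    sigma = float(baseline.get("sigma", 0.3))
    if median <= 0:
        raise ValueError("baseline clearance must have positive support")
    return median * np.exp(sigma * rng.standard_normal())


def simulate_runoff_cohort(preset: RunoffPreset, baseline_clearance: dict,
                           n_mrna: int, dt_s: float = 10.0,
                           window_s: float = 1800.0, seed: int = 0,
                           tls_level: float = 10.0,
                           noise_frac: float = 0.03,
                           field_px: float = 256.0,
                           min_sep_px: float = 10.0) -> RunoffCohort:
    """Simulate translation-site runoff traces after an initiation block.

    Non-damaged mRNAs decay linearly so the translation-site signal
    crosses 10% of its plateau at the true clearance time (baseline draw
    times ``clearance_scale``).  Damaged mRNAs keep their plateau for the
    whole window, and a ``znf_on_damaged`` fraction of them carries a
    persistent bound-protein trace.  The damaged and protein-positive
    fractions are the observed cohort fractions of the emulated assay,
    so they are assigned as balanced counts (``round(frac * n)``
    molecules, randomly placed), not independent per-molecule coin
    flips.  The mRNA trace persists throughout.
    """
    _validate_window(n_mrna, window_s, dt_s)
    n_frames = int(round(window_s / dt_s))
    times = np.arange(n_frames) * dt_s
    ss = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(ss.spawn(1)[0])
    mol_seeds = ss.spawn(n_mrna + 1)[1:] if n_mrna else []
    field_px = max(field_px, np.ceil(np.sqrt(n_mrna) * 1.8 * min_sep_px) + 16)
    anchors = (_place_anchors(n_mrna, field_px, min_sep_px, place_rng)
               if n_mrna else np.zeros((0, 2)))
    # balanced assignment of damaged / protein-positive subpopulations
    perm = place_rng.permutation(n_mrna)
    n_damaged = int(round(preset.damaged_frac * n_mrna))
    damaged_ids = set(perm[:n_damaged].tolist())
    n_znf = int(round(preset.znf_on_damaged * n_damaged))
    znf_ids = set(perm[:n_znf].tolist())

    truth = GroundTruth(window_s=window_s, dt_s=dt_s)
    positions = np.zeros((n_mrna, n_frames, 2))
    mrna_traces = np.zeros((n_mrna, n_frames))
    tls_traces = np.zeros((n_mrna, n_frames))
    protein_traces = np.zeros((n_mrna, n_frames))

    for i in range(n_mrna):
        rng = np.random.default_rng(mol_seeds[i])
        damaged = i in damaged_ids
        znf = i in znf_ids
        if damaged:
            clearance = float("inf")
            ramp = np.full(n_frames, tls_level)
        else:
            clearance = _draw_clearance(baseline_clearance, rng) \
                * preset.clearance_scale
            t_end = clearance / 0.9   # 10%-of-max crossing at `clearance`
            ramp = tls_level * np.clip(1.0 - times / t_end, 0.0, None)
        noise = noise_frac * tls_level
        positions[i] = _ou_trajectory(anchors[i], n_frames, dt_s, rng)
        tls_traces[i] = ramp + rng.normal(0.0, noise, n_frames)
        mrna_traces[i] = 1.0 + rng.normal(0.0, noise_frac, n_frames)
        protein_traces[i] = (1.0 if znf else 0.0) \
            + rng.normal(0.0, 0.1, n_frames)
        truth.molecules.append(MoleculeTruth(
            mrna_id=i, anchor=anchors[i], translating=True, damaged=damaged,
            znf_bound=znf, clearance_time_s=clearance,
            clearance_censored=not np.isfinite(clearance)
            or clearance >= window_s))
        if znf:
            truth.episodes.append(Episode(
                mrna_id=i, site=0, t_start=0.0, t_end=window_s,
                duration_s=np.inf, labeled=True, censored_end=True))

    return RunoffCohort(preset=preset, window_s=window_s, dt_s=dt_s,
                        times=times, positions=positions,
                        mrna_traces=mrna_traces, tls_traces=tls_traces,
                        protein_traces=protein_traces, truth=truth)


def draw_nap_counts(mean: float | str, n: int, rng: np.random.Generator,
                    shape: float = 4.0) -> np.ndarray:
    """Draw right-skewed nascent-peptide counts (gamma, shape 4).

    ``mean`` may be a preset name (``"minus_uv"``/``"plus_uv"``) or a
    numeric mean.
    """
    if isinstance(mean, str):
        mean = NAP_PRESETS[mean]
    if mean <= 0:
        raise ValueError("NAP mean must be > 0")
    return rng.gamma(shape, mean / shape, size=n)


def _place_3d(n: int, shape_zyx: tuple[int, int, int], min_sep_px: float,
              rng: np.random.Generator, margin: float = 8.0,
              avoid: Optional[np.ndarray] = None,
              max_tries: int = 50000) -> np.ndarray:
    nz, ny, nx = shape_zyx
    zmargin = min(2.0, (nz - 1) / 3.0)
    pts: list[np.ndarray] = []
    existing = [] if avoid is None or not len(avoid) else list(avoid)
    tries = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, nx - margin),
                         rng.uniform(margin, ny - margin),
                         rng.uniform(zmargin, nz - 1 - zmargin)])
        ok = all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep_px
                 for p in pts + existing)
        if ok:
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError("field too small to place spots without overlap")
    return np.array(pts).reshape(n, 3)


def simulate_smfish_field(n_single: int, nap_counts, cfg: RenderConfig,
                          seed: int = 0, n_z: int = 9,
                          z_step_nm: float = 300.0,
                          mrna_unit: float = 1.0
                          ) -> tuple[ImageStack, ImageStack, np.ndarray,
                                     FishTruth]:
    """Render one fixed-cell 3D two-channel field (one cell per field).

    The protein channel holds ``n_single`` unit-intensity single proteins
    plus one translation site per entry of ``nap_counts`` at
    ``nap_counts[i]`` units; every translation site sits within half a
    pixel of an mRNA-channel spot.  Returns (mRNA stack, protein stack,
    cell mask, truth); the mask covers all spots.
    """
    nap_counts = np.asarray(nap_counts, dtype=float)
    if np.any(nap_counts <= 0):
        raise ValueError("nap_counts must all be > 0")
    if n_single < 0:
        raise ValueError("n_single must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (n_z, cfg.field_px, cfg.field_px)

    n_tls = len(nap_counts)
    mrna_xyz = _place_3d(n_tls, shape, min_sep_px=8.0, rng=rng)
    # translation sites sit on their mRNA (sub-pixel offset)
    tls_xyz = mrna_xyz + np.column_stack([
        rng.uniform(-0.5, 0.5, n_tls), rng.uniform(-0.5, 0.5, n_tls),
        rng.uniform(-0.3, 0.3, n_tls)])
    single_xyz = _place_3d(n_single, shape, min_sep_px=8.0, rng=rng,
                           avoid=mrna_xyz)

    mrna_img = np.full(shape, float(cfg.background_mean))
    prot_img = np.full(shape, float(cfg.background_mean))
    for (x, y, z) in mrna_xyz:
        add_spot_3d(mrna_img, x, y, z, mrna_unit * cfg.photons_per_unit,
                    cfg.psf_sigma_px, cfg.psf_sigma_z_px)
    for (x, y, z), nap in zip(tls_xyz, nap_counts):
        add_spot_3d(prot_img, x, y, z, nap * cfg.photons_per_unit,
                    cfg.psf_sigma_px, cfg.psf_sigma_z_px)
    for (x, y, z) in single_xyz:
        add_spot_3d(prot_img, x, y, z, cfg.photons_per_unit,
                    cfg.psf_sigma_px, cfg.psf_sigma_z_px)
    mrna_img = apply_noise(mrna_img, cfg, rng)
    prot_img = apply_noise(prot_img, cfg, rng)

    mask = np.zeros((cfg.field_px, cfg.field_px), dtype=int)
    mask[2:-2, 2:-2] = 1   # one cell covering the imaged area

    truth = FishTruth(mrna_xyz=mrna_xyz, tls_xyz=tls_xyz,
                      tls_mrna_index=np.arange(n_tls),
                      single_xyz=single_xyz, nap_counts=nap_counts,
                      degenerate=n_single == 0)
    mk = dict(pixel_size_nm=cfg.pixel_size_nm, frame_interval_s=0.0,
              z_step_nm=z_step_nm)
    return (ImageStack(data=mrna_img, channel="mrna", **mk),
            ImageStack(data=prot_img, channel="protein", **mk),
            mask, truth)


def cohort_to_tracks(cohort, seed: int = 0, jitter_px: float = 0.15,
                     channel_jitter_px: float = 0.2) -> dict[str, list[Track]]:
    """Turn a trace-level cohort into per-channel track objects.

    This is the trace-level observation model: localization noise is
    added to the true positions, the mRNA (and, for translating mRNAs,
    translation-site) tracks span the whole window, and each labeled
    binding episode that covers at least one frame instant becomes a
    protein track at the mRNA's position plus a small channel offset.
    """
    rng = np.random.default_rng(seed)
    times = cohort.times
    n_frames = len(times)
    mrna_tracks, tls_tracks, protein_tracks = [], [], []
    next_id = 0
    for mol in cohort.truth.molecules:
        i = mol.mrna_id
        jit = rng.normal(0.0, jitter_px, size=(n_frames, 2))
        spots = [(f, Spot(frame=f, x=cohort.positions[i, f, 0] + jit[f, 0],
                          y=cohort.positions[i, f, 1] + jit[f, 1],
                          amplitude=1.0, sigma_x=1.3, sigma_y=1.3,
                          background=0.0,
                          integrated_intensity=float(cohort.mrna_traces[i, f]),
                          channel="mrna"))
                 for f in range(n_frames)]
        mrna_tracks.append(Track(id=i, channel="mrna", spots=spots))
        if mol.translating:
            tspots = [(f, Spot(frame=f,
                               x=cohort.positions[i, f, 0]
                               + rng.normal(0, channel_jitter_px),
                               y=cohort.positions[i, f, 1]
                               + rng.normal(0, channel_jitter_px),
                               amplitude=1.0, sigma_x=1.3, sigma_y=1.3,
                               background=0.0,
                               integrated_intensity=float(
                                   cohort.tls_traces[i, f]),
                               channel="tls"))
                      for f in range(n_frames)]
            tls_tracks.append(Track(id=10_000 + i, channel="tls",
                                    spots=tspots))
        for ep in cohort.truth.episodes_for(i):
            if not ep.labeled:
                continue
            frames = np.nonzero((times >= ep.t_start)
                                & (times < ep.t_end))[0]
            if len(frames) == 0:
                continue
            pspots = [(int(f), Spot(
                frame=int(f),
                x=cohort.positions[i, f, 0] + rng.normal(0, channel_jitter_px),
                y=cohort.positions[i, f, 1] + rng.normal(0, channel_jitter_px),
                amplitude=1.0, sigma_x=1.3, sigma_y=1.3, background=0.0,
                integrated_intensity=float(cohort.protein_traces[i, f]),
                channel="protein")) for f in frames]
            protein_tracks.append(Track(id=20_000 + next_id,
                                        channel="protein", spots=pspots))
            next_id += 1
    return {"mrna": mrna_tracks, "tls": tls_tracks,
            "protein": protein_tracks}
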