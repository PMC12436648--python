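"""Kinetic and runoff presets used as simulation ground truth.

The presets encode the measured quantities of the membrane-tethered
single-mRNA assays this package analyzes: mean residence time of a
single coat-protein binder on a 1x stem-loop site (3.6 s, exponential),
per-mRNA engagement fractions for the 1x/3x/12x binding-site calibration
ladder (0.50 / 0.80 / 0.95), E3-ligase recruitment to translating
reporter mRNAs (0.8 for the stalling reporter, 0.1 for the no-insert
control), transient recruitment durations averaging 3.5 min inside a
5-min window, a 1.5-fold clearance-rate change under ligase
overexpression, and a 10% runoff-resistant subpopulation of which half
carry ligase signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "KineticPreset",
    "RunoffPreset",
    "KINETIC_PRESETS",
    "RUNOFF_PRESETS",
    "BASELINE_CLEARANCE",
    "NAP_PRESETS",
    "get_kinetic_preset",
    "get_runoff_preset",
]


@dataclass(frozen=True)
class KineticPreset:
    """Ground-truth binding kinetics for one simulated condition.

    ``dwell_model`` selects how episodes are drawn:

    - ``"renewal"``: per-site alternating on/off renewal process;
      on-times exponential with mean ``mean_on_s``, off-times exponential
      with rate ``duty_or_kon``.
    - ``"episode_mixture"``: one recruitment per engaged mRNA, either
      persistent past the window (probability ``persistent_frac``) or
      transient with mean duration ``transient_mean_min`` minutes; the
      transient duration is drawn from a scaled Beta on (0, window) so
      that the mean of in-window durations equals the preset value.
    """

    name: str
    p_engaged: float
    n_sites: int = 1
    mean_on_s: float = 3.6
    duty_or_kon: float = 1.0 / 90.0
    persistent_frac: float = 0.0
    transient_mean_min: float = 0.0
    label_eff: float = 1.0
    dwell_model: str = "renewal"
    # engagement presets guarantee one qualifying-length episode per
    # engaged mRNA (memoryless shift: min_qualify_s + Exp(mean_on_s))
    ensure_qualifying: bool = False
    min_qualify_s: float = 12.0

    def __post_init__(self) -> None:
        for p in ("p_engaged", "persistent_frac", "label_eff"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_sites > 0 and self.mean_on_s <= 0:
            raise ValueError("mean_on_s must be > 0 when n_sites > 0")
        if self.duty_or_kon < 0:
            raise ValueError("duty_or_kon must be >= 0")
        if (self.dwell_model == "episode_mixture"
                and self.persistent_frac < 1 and self.transient_mean_min <= 0):
            raise ValueError("transient_mean_min must be > 0 when "
                             "persistent_frac < 1")
        if self.dwell_model not in ("renewal", "episode_mixture"):
            raise ValueError(f"unknown dwell_model {self.dwell_model!r}")


@dataclass(frozen=True)
class RunoffPreset:
    """Ground truth for a harringtonine-runoff cohort.

    The translation-site signal of a non-resistant mRNA decays as a
    linear ramp from its plateau to zero, crossing 10% of maximum at the
    true clearance time (uniform ribosome flux gives a linear decay).
    ``clearance_scale`` multiplies the baseline clearance-time draw, so a
    preset pair differing only in scale models a rate change.
    """

    name: str
    clearance_scale: float = 1.0
    damaged_frac: float = 0.0
    znf_on_damaged: float = 0.0

    def __post_init__(self) -> None:
        if self.clearance_scale <= 0:
            raise ValueError("clearance_scale must be > 0")
        for p in ("damaged_frac", "znf_on_damaged"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")


_ZNF_DWELL = dict(dwell_model="episode_mixture", persistent_frac=1.0 / 3.0,
                  transient_mean_min=3.5, mean_on_s=210.0)

KINETIC_PRESETS: dict[str, KineticPreset] = {
    # dwell-time measurement condition (1x site, exponential on-times)
    "pbs_1x_kinetics": KineticPreset("pbs_1x_kinetics", p_engaged=0.5,
                                     n_sites=1, mean_on_s=3.6,
                                     duty_or_kon=1.0 / 90.0),
    # engagement ladder (fraction of mRNAs with >=1 qualifying event)
    "pbs_1x": KineticPreset("pbs_1x", p_engaged=0.50, n_sites=1,
                            ensure_qualifying=True),
    "pbs_3x": KineticPreset("pbs_3x", p_engaged=0.80, n_sites=3,
                            ensure_qualifying=True),
    "pbs_12x": KineticPreset("pbs_12x", p_engaged=0.95, n_sites=12,
                             ensure_qualifying=True),
    # E3-ligase recruitment to translating reporters
    "polya_znf": KineticPreset("polya_znf", p_engaged=0.80, **_ZNF_DWELL),
    "no_insert_znf": KineticPreset("no_insert_znf", p_engaged=0.10,
                                   **_ZNF_DWELL),
    # pure transient component, for dwell-duration recovery
    "polya_znf_transient": KineticPreset("polya_znf_transient", p_engaged=1.0,
                                         dwell_model="episode_mixture",
                                         persistent_frac=0.0,
                                         transient_mean_min=3.5,
                                         mean_on_s=210.0),
}

RUNOFF_PRESETS: dict[str, RunoffPreset] = {
    "runoff_wt": RunoffPreset("runoff_wt", clearance_scale=1.0),
    "runoff_oe": RunoffPreset("runoff_oe", clearance_scale=1.0 / 1.5),
    "runoff_damaged": RunoffPreset("runoff_damaged", clearance_scale=1.0,
                                   damaged_frac=0.10, znf_on_damaged=0.50),
}

# baseline clearance-time distributions (positive support)
BASELINE_CLEARANCE: dict[str, dict] = {
    "polya60": {"dist": "lognormal", "median_s": 600.0, "sigma": 0.3},
    "no_insert": {"dist": "lognormal", "median_s": 180.0, "sigma": 0.4},
}

# nascent-peptide count presets for the smFISH assay (gamma, shape 4)
NAP_PRESETS: dict[str, float] = {"minus_uv": 40.3, "plus_uv": 48.1}


def get_kinetic_preset(name: str, **overrides) -> KineticPreset:
    preset = KINETIC_PRESETS[name]
    return replace(preset, **overrides) if overrides else preset


def get_runoff_preset(name: str, **overrides) -> RunoffPreset:
    preset = RUNOFF_PRESETS[name]
    return replace(preset, **overrides) if overrides else preset
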