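"""Cohort-simulation and pipeline configuration.

All tunable parameters of the synthetic cohort generator and the analysis
stages live in a single :class:`CohortConfig` so that a run is fully
described by one YAML file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: physical scan field of the wide-angle protocol, mm (width, height)
FIELD_MM: tuple[float, float] = (12.0, 9.0)

#: diameter of the clinically standard circumpapillary circle, mm
CPRNFL_CIRCLE_DIAMETER_MM: float = 3.45


@dataclass
class CohortConfig:
    """Stated world of the synthetic longitudinal cohort.

    Defaults mirror the study design this generator emulates: 93 glaucoma
    participants (179 eyes) and 28 healthy participants (56 eyes), imaged
    every 3 months for 2 years on a 12.0 x 9.0 mm wide-angle field.
    """

    # ---- cohort structure -------------------------------------------------
    n_glaucoma_participants: int = 93
    n_healthy_participants: int = 28
    #: probability a participant contributes two eyes; counts are assigned
    #: deterministically (round(p * n) participants get two eyes) so the
    #: default reproduces the 179 / 56 eye totals exactly.
    p_two_eyes_glaucoma: float = 86.0 / 93.0
    p_two_eyes_healthy: float = 1.0
    n_visits: int = 9
    visit_interval_months: float = 3.0

    # ---- geometry ---------------------------------------------------------
    grid_h: int = 120
    grid_w: int = 160
    field_mm: tuple[float, float] = FIELD_MM

    # ---- demographics (years) --------------------------------------------
    age_mean_glaucoma: float = 65.0
    age_mean_healthy: float = 48.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (18.0, 95.0)

    # ---- healthy template -------------------------------------------------
    #: target mean circumpapillary thickness of the healthy template, um
    template_cprnflt_um: float = 95.0

    # ---- glaucomatous damage ----------------------------------------------
    #: baseline severity at the damage-pattern peak, um: truncated N(mean, sd)
    severity_mean_um: float = 30.0
    severity_sd_um: float = 12.0
    severity_bounds_um: tuple[float, float] = (5.0, 70.0)
    #: mixture over damage patterns (inferior-arcuate, superior-arcuate,
    #: diffuse-macular)
    pattern_mixture_weights: tuple[float, ...] = (0.4, 0.4, 0.2)

    # ---- longitudinal change ----------------------------------------------
    progressing_fraction: float = 0.15
    #: slope at pattern peak for progressing eyes, um/year (negative thins)
    progression_slope_mean: float = -4.0
    progression_slope_sd: float = 1.5
    #: slope magnitude separating progressing from stable truth labels
    progression_slope_threshold: float = -1.5
    #: global age-related thinning of healthy (and stable) eyes, um/year
    healthy_slope_mean: float = -0.3
    healthy_slope_sd: float = 0.25
    #: optional coupling of progression slope to baseline severity
    #: (um/year extra slope per um of baseline severity; 0 = uncoupled)
    slope_severity_coupling: float = 0.0

    # ---- noise ------------------------------------------------------------
    #: per-pixel thickness noise before sigma=1 px smoothing, um
    measurement_noise_sd: float = 2.0
    #: instrument noise on the circle-scan mean thickness, um, *on top of*
    #: the per-pixel noise channel that already propagates into the circle
    #: mean (the combined test-retest SD is ~1 um, typical of SD-OCT global
    #: RNFL reproducibility)
    cprnflt_noise_sd: float = 0.5

    # ---- functional link --------------------------------------------------
    #: dB of visual-field mean deviation lost per um of mean structural loss
    sap_md_per_um: float = 0.35
    fdt_md_per_um: float = 0.30
    sap_psd_per_um: float = 0.20
    fdt_psd_per_um: float = 0.18
    md_noise_sd: float = 1.0
    psd_noise_sd: float = 0.6

    # ---- per-scan misalignment -------------------------------------------
    max_translation_px: float = 5.0
    max_rotation_deg: float = 3.0
    max_scale_dev: float = 0.03
    os_fraction: float = 0.5

    # ---- analysis knobs ---------------------------------------------------
    n_components: int = 10
    n_boot: int = 2000
    seed: int = 0

    # ------------------------------------------------------------------ api
    def __post_init__(self) -> None:
        if self.n_glaucoma_participants < 1 or self.n_healthy_participants < 1:
            raise ValueError("participant counts must be >= 1")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if self.visit_interval_months <= 0:
            raise ValueError("visit_interval_months must be > 0")
        for p in (self.p_two_eyes_glaucoma, self.p_two_eyes_healthy,
                  self.progressing_fraction, self.os_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p!r} outside [0, 1]")
        if self.grid_h < 48 or self.grid_w < 64:
            raise ValueError("grid must be at least 64 x 48 (w x h)")
        if min(self.field_mm) <= 0:
            raise ValueError("field_mm must be positive")
        w = self.pattern_mixture_weights
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("pattern_mixture_weights must be non-negative")

    @property
    def um_per_px(self) -> tuple[float, float]:
        """Physical pixel pitch (x, y) in micrometres."""
        return (self.field_mm[0] * 1000.0 / self.grid_w,
                self.field_mm[1] * 1000.0 / self.grid_h)

    @property
    def visit_months(self) -> list[float]:
        return [i * self.visit_interval_months for i in range(self.n_visits)]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        # YAML round-trips tuples as lists; normalised on load
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("field_mm", "age_bounds", "severity_bounds_um",
                    "pattern_mixture_weights"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
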