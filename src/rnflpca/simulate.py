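"""Synthetic longitudinal RNFL cohort generator.

Emulates the statistical structure of a glaucoma imaging study: two
diagnostic groups with an age confound, wide-angle thickness maps built
from a healthy template minus spatially structured damage (inferior /
superior arcuate bundles, diffuse macular thinning), eye-level linear
progression, functional measures (visual-field MD / PSD) linked to
structural loss, and per-scan acquisition misalignment plus left-eye
mirroring. Ground truth (patterns, severities, slopes, applied transforms)
is recorded so downstream stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import brentq

from .config import CohortConfig
from .maps import ThicknessMap, extract_mean_cprnflt
from .registration import canonical_landmarks, unflip
from .transforms import SimilarityTransform

PATTERN_NAMES = ("inferior_arcuate", "superior_arcuate", "diffuse_macular")


# ---------------------------------------------------------------------------
# geometry helpers


def _grid_mm(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x_mm, y_mm) coordinate grids for the configured raster."""
    ux, uy = config.um_per_px
    x = np.arange(config.grid_w) * ux / 1000.0
    y = np.arange(config.grid_h) * uy / 1000.0
    return np.meshgrid(x, y)


def _landmarks_mm(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    fovea_px, onh_px = canonical_landmarks((config.grid_h, config.grid_w))
    ux, uy = config.um_per_px
    to_mm = np.array([ux, uy]) / 1000.0
    return fovea_px * to_mm, onh_px * to_mm


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
            n: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _curve_weight(xx: np.ndarray, yy: np.ndarray, curve: np.ndarray,
                  sigma_mm: float, decay: float = 1.0) -> np.ndarray:
    """Gaussian-profile weight around a sampled curve, fading along it."""
    w = np.zeros_like(xx)
    n = len(curve)
    amps = np.exp(-decay * np.linspace(0.0, 1.0, n))
    for (cx, cy), a in zip(curve, amps):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        np.maximum(w, a * np.exp(-d2 / (2.0 * sigma_mm ** 2)), out=w)
    return w


def _arcuate_curves(config: CohortConfig) -> dict[str, np.ndarray]:
    """Superior / inferior nerve-fibre bundle arcs (quadratic Beziers) in mm.

    Arcs leave the optic nerve head, sweep around the macula and fade toward
    the temporal raphe — the coarse geometry of the arcuate bundles.
    """
    fovea, onh = _landmarks_mm(config)
    out = {}
    for name, sgn in (("superior", -1.0), ("inferior", 1.0)):
        p0 = onh + np.array([0.0, sgn * 0.4])
        p1 = onh + np.array([1.6, sgn * 3.0])
        p2 = fovea + np.array([2.4, sgn * 1.3])
        out[name] = _bezier(p0, p1, p2)
    return out


# ---------------------------------------------------------------------------
# healthy template


def generate_template_map(config: CohortConfig,
                          arcuate_amplitude: float = 1.0,
                          foveal_depth: float = 0.92) -> ThicknessMap:
    """Healthy right-eye RNFL thickness prior on the configured grid.

    Peripapillary annulus with superior/inferior ("double hump") angular
    modulation, arcuate bundles converging on the optic nerve head, and a
    thin fovea. The overall amplitude is tuned by 1-D root finding so the
    mean thickness on the standard 3.45 mm circumpapillary circle matches
    ``config.template_cprnflt_um``.

    ``arcuate_amplitude=0`` (with ``foveal_depth=0``) degenerates to a
    radially symmetric ring about the ONH, useful as a geometric control.
    """
    if config.grid_w < 64 or config.grid_h < 48:
        raise ValueError("degenerate grid: need at least 64 x 48 px")
    xx, yy = _grid_mm(config)
    fovea, onh = _landmarks_mm(config)

    r_onh = np.hypot(xx - onh[0], yy - onh[1])
    phi = np.arctan2(yy - onh[1], xx - onh[0])
    r_fov = np.hypot(xx - fovea[0], yy - fovea[1])

    ring_radius_mm, ring_sigma_mm = 1.7, 0.8
    ring = np.exp(-(r_onh - ring_radius_mm) ** 2 / (2 * ring_sigma_mm ** 2))
    modulation = 1.0 + 0.9 * arcuate_amplitude * np.sin(phi) ** 2
    structure = ring * modulation

    curves = _arcuate_curves(config)
    for curve in curves.values():
        structure = structure + 0.9 * arcuate_amplitude * _curve_weight(
            xx, yy, curve, sigma_mm=0.7, decay=1.2)

    pit = 1.0 - foveal_depth * np.exp(-r_fov ** 2 / (2 * 0.45 ** 2))
    background = 22.0 * np.exp(-r_onh / 9.0)

    fovea_px, onh_px = canonical_landmarks((config.grid_h, config.grid_w))

    def build(amp: float) -> np.ndarray:
        return pit * (background + amp * structure)

    def circle_mean(amp: float) -> float:
        tm = ThicknessMap(values=build(amp), laterality="OD",
                          fovea_xy=tuple(fovea_px), onh_xy=tuple(onh_px),
                          um_per_px=config.um_per_px, od_oriented=True)
        return extract_mean_cprnflt(tm)

    target = config.template_cprnflt_um
    amp = brentq(lambda a: circle_mean(a) - target, 0.0, 400.0, xtol=1e-6)
    return ThicknessMap(values=build(amp), laterality="OD",
                        fovea_xy=tuple(fovea_px), onh_xy=tuple(onh_px),
                        um_per_px=config.um_per_px, od_oriented=True)


def damage_patterns(config: CohortConfig) -> dict[str, np.ndarray]:
    """Smooth damage-pattern masks in [0, 1] on the template grid.

    ``inferior_arcuate`` / ``superior_arcuate`` follow the bundle arcs;
    ``diffuse_macular`` is a broad Gaussian centred between macula and disc.
    """
    xx, yy = _grid_mm(config)
    fovea, onh = _landmarks_mm(config)
    # damage arcs enter the disc at the superior / inferior poles (0.8 mm
    # off-centre) so the two arcuate patterns are nearly orthogonal
    pats = {}
    for key, (name, sgn) in {"superior_arcuate": ("superior", -1.0),
                             "inferior_arcuate": ("inferior", 1.0)}.items():
        p0 = onh + np.array([0.0, sgn * 0.8])
        p1 = onh + np.array([1.6, sgn * 3.0])
        p2 = fovea + np.array([2.4, sgn * 1.3])
        pats[key] = _curve_weight(xx, yy, _bezier(p0, p1, p2),
                                  sigma_mm=0.8, decay=0.8)
    pats = {k: pats[k] for k in ("inferior_arcuate", "superior_arcuate")}
    # macular thinning centred on the fovea, largely distal to the
    # peripapillary measurement circle
    r = np.hypot(xx - fovea[0], yy - fovea[1])
    pats["diffuse_macular"] = np.exp(-r ** 2 / (2 * 2.0 ** 2))
    return {k: v / v.max() for k, v in pats.items()}


# ---------------------------------------------------------------------------
# cohort containers


@dataclass
class GroundTruth:
    """Generative truth for parameter-recovery scoring."""

    eyes: pd.DataFrame        # eye_id, group, pattern, severity_um, slope,
                              # slope_cprnflt, progressing
    scans: pd.DataFrame       # scan_id + applied misalignment + flipped flag
    template: ThicknessMap
    patterns: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    """Longitudinal cohort: one table row per scan plus the map store."""

    table: pd.DataFrame
    maps: dict[str, ThicknessMap]
    config: CohortConfig

    @property
    def participants(self) -> np.ndarray:
        return self.table["participant_id"].unique()

    def scans_of(self, participant_id: str) -> pd.DataFrame:
        return self.table[self.table["participant_id"] == participant_id]

    def baseline(self) -> pd.DataFrame:
        m0 = self.table["visit_month"].min()
        return self.table[self.table["visit_month"] == m0]


TABLE_COLUMNS = ["scan_id", "participant_id", "eye_id", "laterality", "group",
                 "age", "sex", "visit_month", "sap_md", "sap_psd", "fdt_md",
                 "fdt_psd", "mean_cprnflt"]


# ---------------------------------------------------------------------------
# generation


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size=None) -> np.ndarray:
    """Truncation by redraw (ranges are wide; few redraws needed)."""
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = (x < lo) | (x > hi)
    return x


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, smooth_sigma: float = 1.0) -> np.ndarray:
    """Spatially correlated noise with (approximately) the requested pixel SD."""
    if sd <= 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.normal(0.0, 1.0, shape), smooth_sigma)
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def _misalign(values: np.ndarray, t: SimilarityTransform) -> np.ndarray:
    """Warp with edge extension: the instrument images the whole field."""
    inv = t.inverse().matrix
    a = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset = np.array([inv[1, 2], inv[0, 2]])
    return affine_transform(np.ascontiguousarray(values), a, offset=offset,
                            order=1, mode="nearest")


def _random_misalignment(rng: np.random.Generator,
                         config: CohortConfig,
                         centre: np.ndarray) -> SimilarityTransform:
    """Similarity with rotation/scale about the grid centre."""
    s = 1.0 + rng.uniform(-config.max_scale_dev, config.max_scale_dev)
    theta = np.deg2rad(rng.uniform(-config.max_rotation_deg,
                                   config.max_rotation_deg))
    tx, ty = rng.uniform(-config.max_translation_px,
                         config.max_translation_px, size=2)
    about_centre = SimilarityTransform(s, theta, 0.0, 0.0)
    shift = about_centre.apply(centre) - centre
    return SimilarityTransform(s, theta, float(tx - shift[0]),
                               float(ty - shift[1]))


def _n_two_eyed(n: int, p_two: float) -> int:
    """Deterministic two-eye count so default totals match the study design."""
    return int(round(p_two * n))


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort plus its generative ground truth.

    Reproducible: every random draw descends from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    template = generate_template_map(config)
    patterns = damage_patterns(config)
    pattern_names = list(patterns)
    mix = np.asarray(config.pattern_mixture_weights, dtype=float)
    if len(mix) != len(pattern_names):
        raise ValueError("pattern_mixture_weights must have "
                         f"{len(pattern_names)} entries")
    mix = mix / mix.sum()

    h, w = config.grid_h, config.grid_w
    months = np.asarray(config.visit_months)
    years = months / 12.0
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    # circle geometry for mean cpRNFLt of the clean truth-frame map
    circle_pattern_mean = {
        k: _pattern_circle_mean(v, template) for k, v in patterns.items()}

    rows: list[dict] = []
    maps: dict[str, ThicknessMap] = {}
    eye_rows: list[dict] = []
    scan_rows: list[dict] = []

    groups = ([("G", i, "glaucoma") for i in range(config.n_glaucoma_participants)]
              + [("H", i, "healthy") for i in range(config.n_healthy_participants)])
    n_two = {"glaucoma": _n_two_eyed(config.n_glaucoma_participants,
                                     config.p_two_eyes_glaucoma),
             "healthy": _n_two_eyed(config.n_healthy_participants,
                                    config.p_two_eyes_healthy)}
    counters = {"glaucoma": 0, "healthy": 0}

    for prefix, i, group in groups:
        pid = f"{prefix}{i:03d}"
        age_mean = (config.age_mean_glaucoma if group == "glaucoma"
                    else config.age_mean_healthy)
        age = float(_truncated_normal(rng, age_mean, config.age_sd,
                                      *config.age_bounds))
        sex = "F" if rng.random() < 0.5 else "M"
        two_eyes = counters[group] < n_two[group]
        counters[group] += 1
        lateralities = ["OD", "OS"] if two_eyes else \
            (["OD"] if rng.random() < 0.5 else ["OS"])

        for lat in lateralities:
            eye_id = f"{pid}_{lat}"
            healthy_slope = float(rng.normal(config.healthy_slope_mean,
                                             config.healthy_slope_sd))
            if group == "glaucoma":
                pattern = pattern_names[int(rng.choice(len(mix), p=mix))]
                severity = float(_truncated_normal(
                    rng, config.severity_mean_um, config.severity_sd_um,
                    *config.severity_bounds_um))
                if config.slope_severity_coupling != 0.0:
                    slope = healthy_slope + config.slope_severity_coupling * severity
                elif rng.random() < config.progressing_fraction:
                    slope = float(rng.normal(config.progression_slope_mean,
                                             config.progression_slope_sd))
                    slope = min(slope, config.progression_slope_threshold)
                else:
                    slope = healthy_slope
                progressing = slope <= config.progression_slope_threshold
                pat_mask = patterns[pattern]
                slope_cprnflt = slope * circle_pattern_mean[pattern]
            else:
                pattern, severity = "none", 0.0
                slope = healthy_slope
                progressing = False
                pat_mask = None
                slope_cprnflt = slope
            eye_rows.append(dict(eye_id=eye_id, participant_id=pid,
                                 group=group, pattern=pattern,
                                 severity_um=severity, slope=slope,
                                 slope_cprnflt=slope_cprnflt,
                                 progressing=progressing))

            for month, year in zip(months, years):
                if group == "glaucoma":
                    clean = (template.values
                             - (severity - slope * year) * pat_mask)
                else:
                    clean = template.values + slope * year
                clean = np.maximum(clean, 0.0)
                noisy = np.maximum(
                    clean + _smooth_noise(rng, (h, w),
                                          config.measurement_noise_sd), 0.0)

                # clinical scalars from the truth-frame (pre-misalignment) map
                clean_map = template.copy_with(values=noisy)
                cprnflt = extract_mean_cprnflt(clean_map) + float(
                    rng.normal(0.0, config.cprnflt_noise_sd))
                cprnflt = max(cprnflt, 1.0)
                loss = _sector_loss(template.values, clean, pat_mask)
                sap_md = float(-config.sap_md_per_um * loss
                               + rng.normal(0.0, config.md_noise_sd))
                fdt_md = float(-config.fdt_md_per_um * loss
                               + rng.normal(0.0, config.md_noise_sd))
                sap_psd = max(0.5, float(1.8 + config.sap_psd_per_um * loss
                                         + rng.normal(0.0, config.psd_noise_sd)))
                fdt_psd = max(0.5, float(2.6 + config.fdt_psd_per_um * loss
                                         + rng.normal(0.0, config.psd_noise_sd)))

                t_mis = _random_misalignment(rng, config, centre)
                acq = _misalign(noisy, t_mis)
                fov = tuple(t_mis.apply(np.asarray(template.fovea_xy)))
                onh = tuple(t_mis.apply(np.asarray(template.onh_xy)))
                tmap = ThicknessMap(values=acq, laterality="OD",
                                    fovea_xy=fov, onh_xy=onh,
                                    um_per_px=config.um_per_px,
                                    eye_id=eye_id, participant_id=pid,
                                    visit_month=float(month),
                                    od_oriented=True)
                if lat == "OS":
                    tmap = unflip(tmap.copy_with(laterality="OS"))
                scan_id = tmap.scan_id
                maps[scan_id] = tmap
                scan_rows.append(dict(scan_id=scan_id, eye_id=eye_id,
                                      scale=t_mis.scale, theta=t_mis.theta,
                                      tx=t_mis.tx, ty=t_mis.ty,
                                      flipped=(lat == "OS")))
                rows.append(dict(scan_id=scan_id, participant_id=pid,
                                 eye_id=eye_id, laterality=lat, group=group,
                                 age=age + year, sex=sex,
                                 visit_month=float(month), sap_md=sap_md,
                                 sap_psd=sap_psd, fdt_md=fdt_md,
                                 fdt_psd=fdt_psd, mean_cprnflt=cprnflt))

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    truth = GroundTruth(eyes=pd.DataFrame(eye_rows),
                        scans=pd.DataFrame(scan_rows),
                        template=template, patterns=patterns)
    return Cohort(table=table, maps=maps, config=config), truth


def _pattern_circle_mean(pattern: np.ndarray, template: ThicknessMap) -> float:
    """Mean of a pattern mask on the circumpapillary circle."""
    pat_map = template.copy_with(values=pattern)
    return extract_mean_cprnflt(pat_map)


def _sector_loss(template: np.ndarray, clean: np.ndarray,
                 pattern: np.ndarray | None) -> float:
    """Structural loss driving function: mean deficit within the damaged
    sector (pattern-weighted), or the global mean deficit for healthy eyes."""
    deficit = template - clean
    if pattern is None:
        return float(deficit.mean())
    return float((deficit * pattern).sum() / pattern.sum())


# ---------------------------------------------------------------------------
# measurement-level longitudinal generator (no maps)


def simulate_longitudinal_measurements(
        n_participants: int,
        n_eyes_per_participant: int = 2,
        n_visits: int = 9,
        interval_months: float = 3.0,
        intercept: float = 95.0,
        fixed_slope: float = -0.3,
        sd_participant_intercept: float = 5.0,
        sd_participant_slope: float = 0.15,
        sd_eye_intercept: float = 2.0,
        sd_eye_slope: float = 0.1,
        residual_sd: float = 1.0,
        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal measurements from a nested random-intercept/slope model.

    Useful for exercising the mixed-effects rate machinery at scale without
    simulating images: measurement = (intercept + participant + eye effects)
    + (fixed_slope + participant + eye slope effects) * years + residual.

    Returns ``(visits, truth)`` where truth holds the per-eye latent slope.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(n_visits) * interval_months / 12.0
    rows, truth_rows = [], []
    for i in range(n_participants):
        pid = f"P{i:03d}"
        b0p = rng.normal(0.0, sd_participant_intercept)
        b1p = rng.normal(0.0, sd_participant_slope)
        for e in range(n_eyes_per_participant):
            eye_id = f"{pid}_E{e}"
            b0e = rng.normal(0.0, sd_eye_intercept)
            b1e = rng.normal(0.0, sd_eye_slope)
            slope = fixed_slope + b1p + b1e
            truth_rows.append(dict(eye_id=eye_id, participant_id=pid,
                                   slope=slope))
            vals = (intercept + b0p + b0e + slope * years
                    + rng.normal(0.0, residual_sd, n_visits))
            for m, v in zip(years * 12.0, vals):
                rows.append(dict(participant_id=pid, eye_id=eye_id,
                                 visit_month=float(m), value=float(v)))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - {"scan_id"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
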