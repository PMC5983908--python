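"""Thickness-map container and circumpapillary circle extraction."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import map_coordinates

from .config import CPRNFL_CIRCLE_DIAMETER_MM


@dataclass
class ThicknessMap:
    """Dense RNFL thickness grid (um) over the wide-angle scan field.

    Parameters
    ----------
    values:
        ``(H, W)`` float array of thickness in micrometres. NaN marks pixels
        with no data (e.g. after resampling outside the source frame).
    laterality:
        ``"OD"`` (right) or ``"OS"`` (left) — the imaged eye.
    od_oriented:
        True once the map has been mirrored (if needed) into right-eye
        orientation for pooled analysis.
    fovea_xy, onh_xy:
        Landmark pixel coordinates ``(x, y)`` with origin at the top-left
        pixel centre, x along columns.
    um_per_px:
        Physical pitch ``(x, y)`` in micrometres per pixel.
    """

    values: np.ndarray
    laterality: str
    fovea_xy: tuple[float, float]
    onh_xy: tuple[float, float]
    um_per_px: tuple[float, float]
    eye_id: str = ""
    participant_id: str = ""
    visit_month: float = 0.0
    od_oriented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        h, w = self.values.shape
        for name, (x, y) in (("fovea", self.fovea_xy), ("onh", self.onh_xy)):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"{name} landmark {x, y} outside the grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < -1e-9:
            raise ValueError("thickness values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def scan_id(self) -> str:
        return f"{self.eye_id}_m{self.visit_month:g}"

    def copy_with(self, **kw) -> "ThicknessMap":
        if "values" not in kw:
            kw["values"] = self.values.copy()
        return replace(self, **kw)


def sample_bilinear(values: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``values`` at ``(n, 2)`` pixel coordinates (x, y)."""
    xy = np.asarray(xy, dtype=float)
    coords = np.vstack([xy[:, 1], xy[:, 0]])  # map_coordinates wants (row, col)
    return map_coordinates(values, coords, order=1, mode="constant",
                           cval=np.nan)


def extract_mean_cprnflt(tmap: ThicknessMap,
                         radius_mm: float = CPRNFL_CIRCLE_DIAMETER_MM / 2,
                         n_angles: int = 720) -> float:
    """Mean thickness on the circle of ``radius_mm`` centred on the ONH.

    Emulates the clinically standard circumpapillary circle scan
    (3.45 mm diameter) by averaging bilinear samples at ``n_angles``
    equally spaced angles.
    """
    if n_angles < 256:
        raise ValueError("n_angles must be >= 256")
    ux, uy = tmap.um_per_px
    rx = radius_mm * 1000.0 / ux
    ry = radius_mm * 1000.0 / uy
    cx, cy = tmap.onh_xy
    h, w = tmap.shape
    if cx - rx < 0 or cx + rx > w - 1 or cy - ry < 0 or cy + ry > h - 1:
        raise ValueError("circumpapillary circle exits the scan field")
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    xy = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
    samples = sample_bilinear(tmap.values, xy)
    return float(np.mean(samples))


# ---------------------------------------------------------------------------
# serialisation


def save_npz(tmap: ThicknessMap, path: str | Path) -> None:
    """Canonical on-disk form: float grid plus landmark/laterality metadata."""
    np.savez(
        path,
        values=tmap.values,
        laterality=np.array(tmap.laterality),
        od_oriented=np.array(tmap.od_oriented),
        fovea_xy=np.asarray(tmap.fovea_xy, dtype=float),
        onh_xy=np.asarray(tmap.onh_xy, dtype=float),
        um_per_px=np.asarray(tmap.um_per_px, dtype=float),
        eye_id=np.array(tmap.eye_id),
        participant_id=np.array(tmap.participant_id),
        visit_month=np.array(tmap.visit_month, dtype=float),
    )


def load_npz(path: str | Path) -> ThicknessMap:
    with np.load(path) as z:
        return ThicknessMap(
            values=z["values"],
            laterality=str(z["laterality"]),
            od_oriented=bool(z["od_oriented"]),
            fovea_xy=tuple(z["fovea_xy"]),
            onh_xy=tuple(z["onh_xy"]),
            um_per_px=tuple(z["um_per_px"]),
            eye_id=str(z["eye_id"]),
            participant_id=str(z["participant_id"]),
            visit_month=float(z["visit_month"]),
        )


def export_png16(tmap: ThicknessMap, path: str | Path,
                 scale: float = 10.0) -> None:
    """16-bit PNG export; pixel value = thickness (um) x ``scale``.

    NaN pixels are written as 0. Lossy below 0.1 um at the default scale;
    the NPZ form is canonical.
    """
    v = np.nan_to_num(tmap.values, nan=0.0) * scale
    iio.imwrite(Path(path), np.clip(np.round(v), 0, 65535).astype(np.uint16))
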