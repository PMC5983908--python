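"""Planar similarity transforms (scale, rotation, translation).

The transform maps source pixel coordinates to destination coordinates:

    x' = s * R(theta) @ x + t

Composition, inversion and point application are exact (closed form), which
the registration chain relies on to compose landmark and ECC estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SimilarityTransform:
    scale: float = 1.0
    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    # ------------------------------------------------------------------ core
    @property
    def matrix(self) -> np.ndarray:
        """2x3 affine matrix ``[sR | t]``."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        a = self.scale
        return np.array([[a * c, -a * s, self.tx],
                         [a * s, a * c, self.ty]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform ``(n, 2)`` (or a single ``(2,)``) point array."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        out = p @ m[:, :2].T + m[:, 2]
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return SimilarityTransform(
            scale=self.scale * other.scale,
            theta=_wrap_angle(self.theta + other.theta),
            tx=float(self.apply(np.array([other.tx, other.ty]))[0]),
            ty=float(self.apply(np.array([other.tx, other.ty]))[1]),
        )

    def inverse(self) -> "SimilarityTransform":
        inv_s = 1.0 / self.scale
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        tx = -inv_s * (c * self.tx - s * self.ty)
        ty = -inv_s * (s * self.tx + c * self.ty)
        return SimilarityTransform(inv_s, _wrap_angle(-self.theta), tx, ty)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        """Recover parameters from a 2x3 (or 2x2+t) similarity matrix."""
        m = np.asarray(m, dtype=float)
        a, b = m[0, 0], m[1, 0]
        scale = float(np.hypot(a, b))
        return cls(scale=scale, theta=float(np.arctan2(b, a)),
                   tx=float(m[0, 2]), ty=float(m[1, 2]))

    def is_close(self, other: "SimilarityTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi, pi]."""
    return float(np.arctan2(np.sin(theta), np.cos(theta)))
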