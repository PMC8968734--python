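"""2D rigid transforms and image resampling.

Coordinates are ``(row, col)``, 0-based, origin at the top-left of the
grid. A positive angle rotates counter-clockwise in the usual display
convention (x = col, y = -row); with that convention the rotation matrix
acting on ``(row, col)`` vectors is the standard ``[[c, -s], [s, c]]``.
``tx`` shifts columns and ``ty`` shifts rows. Rotation is taken about the
grid centre ``((H-1)/2, (W-1)/2)`` unless another centre is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation about a grid centre followed by a translation."""

    tx: float = 0.0
    ty: float = 0.0
    angle_deg: float = 0.0

    def rotation(self) -> np.ndarray:
        th = np.deg2rad(self.angle_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.ty, self.tx])

    def apply(self, points: np.ndarray, center) -> np.ndarray:
        """Map ``(N, 2)`` points ``p`` to ``R (p - c) + c + t``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(center, dtype=float)
        return (pts - c) @ self.rotation().T + c + self.translation

    def inverse(self) -> "RigidTransform2D":
        t = -self.rotation().T @ self.translation
        return RigidTransform2D(tx=float(t[1]), ty=float(t[0]),
                                angle_deg=-self.angle_deg)

    def then(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``self`` first, then ``other``."""
        t = other.rotation() @ self.translation + other.translation
        return RigidTransform2D(tx=float(t[1]), ty=float(t[0]),
                                angle_deg=self.angle_deg + other.angle_deg)

    def scaled(self, factor: float) -> "RigidTransform2D":
        """Damped copy with all three parameters multiplied by ``factor``.

        Valid as a first-order damping for small motions; used by the
        iterative registration refinement loop.
        """
        return RigidTransform2D(self.tx * factor, self.ty * factor,
                                self.angle_deg * factor)

    def magnitude(self) -> tuple[float, float]:
        """``(translation_px, |angle_deg|)`` for convergence checks."""
        return float(np.hypot(self.tx, self.ty)), abs(float(self.angle_deg))

    @property
    def is_identity(self) -> bool:
        return self.tx == 0.0 and self.ty == 0.0 and self.angle_deg == 0.0

    def to_dict(self) -> dict:
        return {"tx": float(self.tx), "ty": float(self.ty),
                "angle_deg": float(self.angle_deg)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(tx=float(d["tx"]), ty=float(d["ty"]),
                   angle_deg=float(d["angle_deg"]))


IDENTITY = RigidTransform2D()


def grid_center(shape) -> tuple[float, float]:
    h, w = shape[:2]
    return ((h - 1) / 2.0, (w - 1) / 2.0)


def resample(image: np.ndarray, transform: RigidTransform2D, *,
             order: int = 1, cval: float = 0.0, center=None) -> np.ndarray:
    """Resample ``image`` so its content moves by ``transform``.

    The output satisfies ``out(q) = image(T^{-1}(q))`` with bilinear
    interpolation by default and constant padding outside the grid.
    An exact identity transform returns a bit-identical copy.
    """
    img = np.asarray(image, dtype=float)
    if transform.is_identity:
        return img.copy()
    h, w = img.shape
    if center is None:
        center = grid_center(img.shape)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    src = transform.inverse().apply(pts, center)
    out = ndimage.map_coordinates(img, [src[:, 0], src[:, 1]],
                                  order=order, mode="constant", cval=cval)
    return out.reshape(h, w)
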