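"""Seeded random ellipse phantoms and their analytic fan-beam sinograms.

A phantom is an additive superposition of ellipses with random attenuation
coefficients, sizes, orientations and locations, all contained in the image's
inscribed support disk.  Line integrals through an ellipse have a closed form
(attenuation times chord length), so the exact sinogram is available without
rasterization — the independent oracle for the raster projector.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import List

import numpy as np

from sinoct.geometry import CTImage, FanGeometry, Sinogram

__all__ = [
    "EllipseSpec",
    "EllipsePhantom",
    "analytic_fan_projection",
    "generate_random_phantom",
    "rasterize",
]

#: default random-ellipse distribution parameters (the source protocol leaves
#: these unspecified; they are package conventions, configurable per call)
DEFAULT_N_MIN = 10
DEFAULT_N_MAX = 40
SEMI_AXIS_FRACTIONS = (1.0 / 32.0, 1.0 / 6.0)


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: center (pixels, relative to the image center), semi-axes,
    rotation (radians, counter-clockwise) and additive attenuation."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def max_radius(self) -> float:
        """Largest distance from the ellipse center to its boundary."""
        return max(self.semi_axis_a, self.semi_axis_b)

    @property
    def outer_extent(self) -> float:
        """Upper bound on distance from the image center to the ellipse."""
        return math.hypot(self.center_x, self.center_y) + self.max_radius


@dataclass
class EllipsePhantom:
    """Ordered collection of ellipses plus the raster grid size."""

    ellipses: List[EllipseSpec]
    grid_size: int = 512

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")

    @property
    def support_radius(self) -> float:
        return self.grid_size / 2.0

    def to_json(self) -> str:
        return json.dumps(
            {"grid_size": self.grid_size, "ellipses": [asdict(e) for e in self.ellipses]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EllipsePhantom":
        obj = json.loads(text)
        return cls(
            ellipses=[EllipseSpec(**rec) for rec in obj["ellipses"]],
            grid_size=int(obj["grid_size"]),
        )


def generate_random_phantom(
    seed: int,
    n_ellipses_min: int = DEFAULT_N_MIN,
    n_ellipses_max: int = DEFAULT_N_MAX,
    grid_size: int = 512,
) -> EllipsePhantom:
    """Draw a random phantom of ``Uniform[n_min, n_max]`` ellipses.

    All draws come from ``numpy.random.default_rng(seed)``: identical seed and
    parameters give a bit-identical phantom.  Semi-axes are uniform in
    ``[grid/32, grid/6]``, rotation uniform in ``[0, pi)``, attenuation
    uniform in ``(0, 1]``, and the center is uniform over the disk that keeps
    the whole ellipse inside the inscribed support disk.
    """
    if n_ellipses_min < 1:
        raise ValueError(f"n_ellipses_min must be >= 1, got {n_ellipses_min}")
    if n_ellipses_max < n_ellipses_min:
        raise ValueError(
            f"n_ellipses_max ({n_ellipses_max}) < n_ellipses_min ({n_ellipses_min})"
        )
    if grid_size < 16:
        raise ValueError(f"grid_size must be >= 16, got {grid_size}")
    rng = np.random.default_rng(seed)
    count = int(rng.integers(n_ellipses_min, n_ellipses_max + 1))
    lo, hi = (f * grid_size for f in SEMI_AXIS_FRACTIONS)
    support = grid_size / 2.0
    ellipses = []
    for _ in range(count):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        max_center = support - max(a, b)
        # uniform over the disk of allowed centers
        r = max_center * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        ellipses.append(
            EllipseSpec(
                center_x=r * math.cos(ang),
                center_y=r * math.sin(ang),
                semi_axis_a=a,
                semi_axis_b=b,
                rotation=rng.uniform(0.0, math.pi),
                attenuation=1.0 - rng.uniform(0.0, 1.0),  # uniform in (0, 1]
            )
        )
    return EllipsePhantom(ellipses=ellipses, grid_size=grid_size)


def rasterize(phantom: EllipsePhantom) -> CTImage:
    """Raster the phantom: pixel value = sum of attenuations of ellipses whose
    interior contains the pixel center (no anti-aliasing)."""
    n = phantom.grid_size
    c = (n - 1) / 2.0
    x = np.arange(n) - c
    xx, yy = np.meshgrid(x, x)  # yy varies along axis 0
    img = np.zeros((n, n))
    for e in phantom.ellipses:
        dx = xx - e.center_x
        dy = yy - e.center_y
        ct, st = math.cos(e.rotation), math.sin(e.rotation)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        inside = (u / e.semi_axis_a) ** 2 + (v / e.semi_axis_b) ** 2 <= 1.0
        img[inside] += e.attenuation
    return CTImage(img)


def _chord_lengths(
    e: EllipseSpec,
    origin_x: np.ndarray,
    origin_y: np.ndarray,
    dir_x: np.ndarray,
    dir_y: np.ndarray,
) -> np.ndarray:
    """Chord length of unit-direction rays ``o + t d`` through the ellipse."""
    ct, st = math.cos(e.rotation), math.sin(e.rotation)
    ox = origin_x - e.center_x
    oy = origin_y - e.center_y
    # rotate into the ellipse frame
    oxr = ox * ct + oy * st
    oyr = -ox * st + oy * ct
    dxr = dir_x * ct + dir_y * st
    dyr = -dir_x * st + dir_y * ct
    a2 = e.semi_axis_a**2
    b2 = e.semi_axis_b**2
    qa = dxr * dxr / a2 + dyr * dyr / b2
    qb = 2.0 * (oxr * dxr / a2 + oyr * dyr / b2)
    qc = oxr * oxr / a2 + oyr * oyr / b2 - 1.0
    disc = qb * qb - 4.0 * qa * qc
    hit = disc > 0.0
    return np.where(hit, np.sqrt(np.where(hit, disc, 0.0)) / qa, 0.0)


def analytic_fan_projection(
    phantom: EllipsePhantom, geometry: FanGeometry
) -> Sinogram:
    """Exact fan-beam sinogram of an ellipse phantom (closed-form chords).

    Each entry is the sum over ellipses of attenuation times the length of
    the intersection of the source-to-channel ray with the ellipse.
    """
    fov = geometry.fov_radius()
    for i, e in enumerate(phantom.ellipses):
        if e.outer_extent > fov + 1e-9:
            raise ValueError(
                f"ellipse {i} (extent {e.outer_extent:.2f} px) exceeds the "
                f"geometry field of view (radius {fov:.2f} px)"
            )
    d = geometry.source_distance
    phis = geometry.view_angles
    w = geometry.channel_positions
    ex, ey = np.cos(phis), np.sin(phis)  # (V,)
    sx = d * ex
    sy = d * ey
    # channel points on the isocenter detector, then unit ray directions
    px = w[None, :] * (-ey)[:, None]  # (V, C)
    py = w[None, :] * ex[:, None]
    dirx = px - sx[:, None]
    diry = py - sy[:, None]
    norm = np.sqrt(dirx * dirx + diry * diry)
    dirx /= norm
    diry /= norm
    ox = np.broadcast_to(sx[:, None], dirx.shape)
    oy = np.broadcast_to(sy[:, None], dirx.shape)
    values = np.zeros(dirx.shape)
    for e in phantom.ellipses:
        values += e.attenuation * _chord_lengths(e, ox, oy, dirx, diry)
    return Sinogram(values, phis, geometry, kind="complete")
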