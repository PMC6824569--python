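"""Equi-spaced fan-beam scan geometry, projectors and degradation operators.

Coordinate conventions (used everywhere in this package):

* Image pixel ``(0, 0)`` is top-left; axis 0 is ``y`` (downward), axis 1 is
  ``x`` (rightward).  The rotation center sits at the image center, i.e. pixel
  ``(i, j)`` has physical coordinates ``x = j - (N-1)/2``, ``y = i - (N-1)/2``
  in pixel units.
* View angles increase counter-clockwise in the ``(x, y)`` frame; view ``k``
  of ``n`` over an angular range ``A`` sits at ``k * A / n`` (endpoint
  exclusive, so 720 views over 360 degrees step by 0.5 degrees).
* The X-ray source at angle ``phi`` is at ``D * (cos phi, sin phi)``.  The
  virtual flat detector passes through the rotation center, perpendicular to
  the central ray; detector coordinate ``w`` runs along ``(-sin phi,
  cos phi)`` and channels are centered on the central ray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "CTImage",
    "FanGeometry",
    "Sinogram",
    "backproject",
    "embed_incomplete",
    "forward_project",
    "limit_angle",
    "scaled_geometry",
    "subsample_views",
]


@dataclass(frozen=True)
class FanGeometry:
    """Equi-spaced fan-beam scan description.

    Parameters
    ----------
    source_distance:
        Distance from the X-ray source to the rotation center, in pixels.
    n_views:
        Number of equally spaced views over ``angular_range``.
    angular_range:
        Total scan range in radians (default full rotation).
    n_channels:
        Number of detector channels; must be odd so the detector is symmetric
        about the central ray.
    channel_spacing:
        Channel pitch in pixels on the virtual flat detector through the
        rotation center.
    """

    source_distance: float = 2700.0
    n_views: int = 720
    angular_range: float = 2.0 * math.pi
    n_channels: int = 731
    channel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError(f"n_views must be >= 1, got {self.n_views}")
        if self.n_channels < 3:
            raise ValueError(f"n_channels must be >= 3, got {self.n_channels}")
        if self.n_channels % 2 == 0:
            raise ValueError(
                f"n_channels must be odd (symmetric detector), got {self.n_channels}"
            )
        if self.source_distance <= 0 or self.channel_spacing <= 0:
            raise ValueError("source_distance and channel_spacing must be positive")
        if not 0 < self.angular_range <= 2.0 * math.pi + 1e-12:
            raise ValueError("angular_range must lie in (0, 2*pi]")

    @property
    def view_angles(self) -> np.ndarray:
        """Angles of all views, radians, endpoint-exclusive spacing."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def channel_positions(self) -> np.ndarray:
        """Signed detector coordinates of channel centers, in pixels."""
        half = (self.n_channels - 1) / 2.0
        return (np.arange(self.n_channels) - half) * self.channel_spacing

    @property
    def detector_half_width(self) -> float:
        return (self.n_channels - 1) / 2.0 * self.channel_spacing

    def magnified_radius(self, radius: float) -> float:
        """Detector coordinate of the ray tangent to a centered disk."""
        d = self.source_distance
        if radius >= d:
            raise ValueError("disk radius must be smaller than source distance")
        return radius * d / math.sqrt(d * d - radius * radius)

    def fov_radius(self) -> float:
        """Radius of the centered disk fully covered by every view's fan."""
        w = self.detector_half_width
        d = self.source_distance
        return w * d / math.sqrt(d * d + w * w)

    def validate_for_grid(self, grid_size: int) -> None:
        """Check that a ``grid_size`` image support can be scanned."""
        half = grid_size / 2.0
        if self.source_distance <= half * math.sqrt(2.0):
            raise ValueError(
                "source_distance must exceed the circumscribed image radius "
                f"({half * math.sqrt(2.0):.1f}), got {self.source_distance}"
            )
        if self.detector_half_width < self.magnified_radius(half):
            raise ValueError(
                "detector half-width does not cover the magnified support disk: "
                f"{self.detector_half_width} < {self.magnified_radius(half):.2f}"
            )


def scaled_geometry(grid_size: int, reference_grid: int = 512) -> FanGeometry:
    """Geometry profile scaled from the full-size 512-grid defaults.

    Keeps the source distance proportional to the grid, the angular sampling
    density of 720 views per 512-grid rotation, and derives the channel count
    as ``2 * ceil(magnified circumscribed radius) + 1`` so the detector just
    covers the whole image at unit channel spacing.  ``scaled_geometry(512)``
    reproduces the 720 x 731 default; ``scaled_geometry(128)`` gives the
    180-view x 185-channel desk profile.
    """
    scale = grid_size / reference_grid
    d = 2700.0 * scale
    n_views = max(4, int(round(720 * scale)))
    if grid_size == reference_grid:
        # the published full-size profile (its 731 channels undercut the
        # ceil-derived coverage by one channel pair; kept as printed)
        return FanGeometry(source_distance=d, n_views=n_views, n_channels=731)
    r_circ = grid_size / 2.0 * math.sqrt(2.0)
    w_max = r_circ * d / math.sqrt(d * d - r_circ * r_circ)
    n_channels = 2 * math.ceil(w_max) + 1
    return FanGeometry(source_distance=d, n_views=n_views, n_channels=n_channels)


@dataclass
class CTImage:
    """Square real-valued reconstruction/phantom grid."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"CTImage must be square 2-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTImage contains non-finite values")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


@dataclass
class Sinogram:
    """Views x channels grid with geometry and completeness metadata.

    ``kind`` is one of ``complete``, ``sparse``, ``limited``, ``corrupted``,
    ``restored``.  ``view_indices`` maps each row to its view index in the
    full scan; ``measured_mask`` (set by :func:`embed_incomplete`) flags which
    rows of a full-size grid hold measured data.
    """

    values: np.ndarray
    view_angles: np.ndarray
    geometry: FanGeometry
    kind: str = "complete"
    factor: Optional[int] = None
    max_angle: Optional[float] = None
    view_indices: Optional[np.ndarray] = None
    measured_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.view_angles = np.asarray(self.view_angles, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (views x channels)")
        if self.values.shape[0] != self.view_angles.shape[0]:
            raise ValueError(
                f"row count {self.values.shape[0]} != number of view angles "
                f"{self.view_angles.shape[0]}"
            )
        if self.values.shape[1] != self.geometry.n_channels:
            raise ValueError(
                f"channel count {self.values.shape[1]} != geometry.n_channels "
                f"{self.geometry.n_channels}"
            )
        if self.kind == "complete" and self.values.shape[0] != self.geometry.n_views:
            raise ValueError("complete sinogram must have geometry.n_views rows")
        if self.view_indices is None:
            self.view_indices = np.arange(self.values.shape[0])
        else:
            self.view_indices = np.asarray(self.view_indices)

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def is_full_size(self) -> bool:
        return self.values.shape[0] == self.geometry.n_views


# ---------------------------------------------------------------------------
# projectors


def _ray_samples(geometry: FanGeometry, grid_size: int, step: float = 0.5):
    """Sample points along every (view, channel) ray, for one view at a time.

    Yields ``(points_x, points_y, dt)`` arrays of shape (n_channels,
    n_samples) per view.  Rays are sampled on the fixed interval where they
    cross the circumscribed circle of the image, so every image pixel can
    contribute.
    """
    d = geometry.source_distance
    w = geometry.channel_positions
    r = grid_size / 2.0 * math.sqrt(2.0) + 1.0
    # source->channel unit directions are identical across views up to rotation:
    # in the source frame the ray covers chord of circle radius r
    n_samples = int(math.ceil(2.0 * r / step)) + 1
    for phi in geometry.view_angles:
        ex, ey = math.cos(phi), math.sin(phi)
        ux, uy = -ey, ex
        sx, sy = d * ex, d * ey
        dirx = w * ux - sx
        diry = w * uy - sy
        norm = np.sqrt(dirx * dirx + diry * diry)
        dirx /= norm
        diry /= norm
        # entry/exit parameters of each ray against the circumscribed circle
        # |S + t*dir| = r  ->  t^2 + 2 t (S.dir) + |S|^2 - r^2 = 0
        b = sx * dirx + sy * diry
        disc = b * b - (d * d - r * r)
        valid = disc > 0.0
        sqrt_disc = np.sqrt(np.where(valid, disc, 0.0))
        t0 = -b - sqrt_disc
        t = t0[:, None] + np.linspace(0.0, 2.0 * r, n_samples)[None, :]
        px = sx + t * dirx[:, None]
        py = sy + t * diry[:, None]
        dt = 2.0 * r / (n_samples - 1)
        yield px, py, dt, valid


def _to_index(coord: np.ndarray, grid_size: int) -> np.ndarray:
    return coord + (grid_size - 1) / 2.0


def forward_project(
    image: CTImage, geometry: FanGeometry, step: float = 0.5
) -> Sinogram:
    """Raster fan-beam forward projection (discrete line integrals).

    Each sinogram entry approximates the integral of the image along the
    source-to-channel ray, by sampling the image with bilinear interpolation
    at points spaced ``step`` pixels apart.
    """
    if not isinstance(image, CTImage):
        image = CTImage(np.asarray(image))
    n = image.grid_size
    geometry.validate_for_grid(n)
    img = image.values
    rows = np.empty((geometry.n_views, geometry.n_channels))
    for k, (px, py, dt, valid) in enumerate(_ray_samples(geometry, n, step)):
        # map_coordinates indexes (axis0=y, axis1=x)
        vals = ndimage.map_coordinates(
            img,
            [_to_index(py, n).ravel(), _to_index(px, n).ravel()],
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        ).reshape(px.shape)
        rows[k] = np.where(valid, vals.sum(axis=1) * dt, 0.0)
    return Sinogram(rows, geometry.view_angles, geometry, kind="complete")


def backproject(sino: Sinogram, geometry: FanGeometry, out_size: int) -> CTImage:
    """Exact adjoint (transpose) of :func:`forward_project`.

    Scatters each sinogram value back along its sampled ray with the same
    bilinear weights and step length, so that
    ``<forward_project(I), S> == <I, backproject(S)>`` holds to machine
    precision.  This is the unfiltered, unweighted transpose; the weighted
    pixel-driven back-projection used inside FBP lives in :mod:`sinoct.fbp`.
    """
    if sino.values.shape[0] != geometry.n_views:
        raise ValueError("backproject expects a full-size (embedded) sinogram")
    n = out_size
    out = np.zeros((n, n))
    for k, (px, py, dt, valid) in enumerate(_ray_samples(geometry, n)):
        iy = _to_index(py, n)
        ix = _to_index(px, n)
        w_row = np.where(valid, sino.values[k], 0.0)[:, None] * dt
        w_full = np.broadcast_to(w_row, px.shape).ravel()
        iy = iy.ravel()
        ix = ix.ravel()
        # match the gather exactly: points outside [0, n-1] contribute nothing
        inside = (iy >= 0) & (iy <= n - 1) & (ix >= 0) & (ix <= n - 1)
        iy, ix, w_full = iy[inside], ix[inside], w_full[inside]
        iy0 = np.floor(iy).astype(np.int64)
        ix0 = np.floor(ix).astype(np.int64)
        fy = iy - iy0
        fx = ix - ix0
        for dy, dx, wgt in (
            (0, 0, (1 - fy) * (1 - fx)),
            (0, 1, (1 - fy) * fx),
            (1, 0, fy * (1 - fx)),
            (1, 1, fy * fx),
        ):
            yy = np.minimum(iy0 + dy, n - 1)  # weight is 0 whenever clipped
            xx = np.minimum(ix0 + dx, n - 1)
            np.add.at(out, (yy, xx), w_full * wgt)
    return CTImage(out)


# ---------------------------------------------------------------------------
# degradation operators


def subsample_views(sino: Sinogram, factor: int) -> Sinogram:
    """Keep every ``factor``-th view starting from view 0 (sparse-view CT)."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"sampling factor must be a positive integer, got {factor}")
    if sino.n_views % factor != 0:
        raise ValueError(
            f"factor {factor} does not divide the view count {sino.n_views}"
        )
    if factor == 1:
        return replace(sino)
    idx = np.arange(0, sino.n_views, factor)
    return Sinogram(
        sino.values[idx].copy(),
        sino.view_angles[idx].copy(),
        sino.geometry,
        kind="sparse",
        factor=int(factor),
        view_indices=sino.view_indices[idx].copy(),
    )


def limit_angle(sino: Sinogram, max_angle: float) -> Sinogram:
    """Keep views in the angular sector ``[0, max_angle)`` (limited-angle CT).

    The sector is half-open so that a 720-view scan at 0.5-degree steps
    limited to 120 degrees keeps exactly 240 views.
    """
    if not 0.0 < max_angle <= sino.geometry.angular_range:
        raise ValueError(
            f"max_angle must lie in (0, {sino.geometry.angular_range:.6f}], "
            f"got {max_angle}"
        )
    if math.isclose(max_angle, sino.geometry.angular_range):
        return replace(sino)
    keep = sino.view_angles < max_angle - 1e-12
    return Sinogram(
        sino.values[keep].copy(),
        sino.view_angles[keep].copy(),
        sino.geometry,
        kind="limited",
        max_angle=float(max_angle),
        view_indices=sino.view_indices[keep].copy(),
    )


def embed_incomplete(sino: Sinogram) -> Sinogram:
    """Zero-fill the missing views of an incomplete sinogram.

    Returns a full ``geometry.n_views x n_channels`` grid with measured rows
    copied bit-exactly and a boolean mask recording which rows were measured.
    A complete input is returned unchanged.
    """
    geom = sino.geometry
    if sino.kind == "complete" or (
        sino.is_full_size and sino.kind not in ("sparse", "limited")
    ):
        return sino
    if sino.kind not in ("sparse", "limited"):
        raise ValueError(f"cannot embed sinogram of kind {sino.kind!r}")
    full = np.zeros((geom.n_views, geom.n_channels))
    mask = np.zeros(geom.n_views, dtype=bool)
    full[sino.view_indices] = sino.values
    mask[sino.view_indices] = True
    return Sinogram(
        full,
        geom.view_angles,
        geom,
        kind=sino.kind,
        factor=sino.factor,
        max_angle=sino.max_angle,
        view_indices=np.arange(geom.n_views),
        measured_mask=mask,
    )
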