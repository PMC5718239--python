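"""Marker visibility and artifact statistics.

Two statistics are computed per marker, following the study design:

* contrast-to-noise ratio ``CNR = (S_max - S_bg_mean) / S_bg_sd`` from a
  15 x 15 cm region-of-interest profile around the marker, where S_max is
  the maximum signal produced by the marker and the background statistics
  exclude a disk around the marker so the marker's own artifact does not
  inflate the noise estimate;
* the standard deviation of bilinearly interpolated pixel values along each
  of 1000 rings of radius 1..15 mm centered on the marker (streak-artifact
  profile), summarized by its mean (the artifact index).

Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DataError, GeometryError, UndefinedCNRError
from .image import Image2D

__all__ = [
    "ROIStats",
    "CNRResult",
    "RingProfile",
    "detect_marker_center",
    "roi_stats",
    "compute_cnr",
    "ring_artifact_profile",
    "artifact_index",
]


@dataclass(frozen=True)
class ROIStats:
    """Signal/background statistics of a marker region of interest."""

    s_max: float
    s_bg_mean: float
    s_bg_sd: float
    n_bg: int

    def __post_init__(self) -> None:
        if self.s_bg_sd < 0:
            raise DataError("background SD cannot be negative")
        if self.n_bg < 2:
            raise DataError("background must contain at least 2 pixels")


@dataclass(frozen=True)
class CNRResult:
    marker_id: str
    cnr: float
    roi: ROIStats
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class RingProfile:
    """SD of interpolated intensities along rings of increasing radius."""

    radii: np.ndarray
    sd_per_ring: np.ndarray
    center: tuple[float, float]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.sd_per_ring, dtype=float)
        if r.shape != s.shape or r.ndim != 1 or r.size < 2:
            raise DataError("radii and sd_per_ring must be 1D of equal length >= 2")
        if np.any(np.diff(r) <= 0):
            raise DataError("radii must be strictly increasing")
        if np.any(s < 0):
            raise DataError("ring SDs cannot be negative")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "sd_per_ring", s)


def detect_marker_center(
    image: Image2D,
    approx_center: tuple[float, float],
    search_radius: float,
) -> tuple[float, float]:
    """Subpixel marker center [(y, x), mm] by thresholded intensity centroid.

    Background mean/SD are estimated on an annulus between 1 and 2 search
    radii; pixels inside the search disk brighter than mean + 3 SD are
    weighted by their excess intensity. Falls back to ``approx_center`` if
    no pixel passes the threshold.
    """
    if search_radius <= 0:
        raise GeometryError("search_radius must be positive")
    cy, cx = approx_center
    if not image.contains_point(cy, cx):
        raise GeometryError(f"approx_center {approx_center} outside image")
    # crop to the 2x search-radius window that the stats below can reach
    r0, c0 = image.phys_to_index(cy, cx)
    half = 2.0 * search_radius
    rows = np.arange(max(0, int(np.floor(r0 - half / image.spacing[0]))),
                     min(image.shape[0], int(np.ceil(r0 + half / image.spacing[0])) + 1))
    cols = np.arange(max(0, int(np.floor(c0 - half / image.spacing[1]))),
                     min(image.shape[1], int(np.ceil(c0 + half / image.spacing[1])) + 1))
    image = Image2D(
        pixels=image.pixels[np.ix_(rows, cols)],
        spacing=image.spacing,
        units=image.units,
        origin=image.index_to_phys(rows[0], cols[0]),
    )
    ys, xs = image.index_to_phys(np.arange(image.shape[0]), np.arange(image.shape[1]))
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    r2 = (Y - cy) ** 2 + (X - cx) ** 2
    disk = r2 <= search_radius**2
    annulus = (r2 > search_radius**2) & (r2 <= (2.0 * search_radius) ** 2)
    if annulus.sum() < 2:
        annulus = ~disk
    bg = image.pixels[annulus]
    thresh = bg.mean() + 3.0 * bg.std(ddof=1)
    hot = disk & (image.pixels > thresh)
    if not hot.any():
        return (float(cy), float(cx))
    w = image.pixels[hot] - thresh
    return (float(np.average(Y[hot], weights=w)), float(np.average(X[hot], weights=w)))


def roi_stats(
    image: Image2D,
    center: tuple[float, float],
    roi_half_width: float = 75.0,
    exclusion_radius: float = 7.5,
    signal_radius: float | None = None,
    exclude_centers: "list[tuple[float, float]] | None" = None,
) -> ROIStats:
    """Statistics of a square ROI (clipped to the image) around ``center``.

    ``s_max`` is the maximum over the ROI, or over a disk of
    ``signal_radius`` around the center when given (so a neighboring
    marker's peak cannot masquerade as this marker's signal). Background
    mean/SD use ROI pixels farther than ``exclusion_radius`` from the
    center -- and from every point in ``exclude_centers`` (other markers
    inside the ROI, whose signal would otherwise inflate the noise
    estimate). Sample SD; the clipped ROI must retain >= 100 pixels.
    """
    cy, cx = center
    ys, xs = image.index_to_phys(np.arange(image.shape[0]), np.arange(image.shape[1]))
    row_in = np.abs(ys - cy) <= roi_half_width
    col_in = np.abs(xs - cx) <= roi_half_width
    if row_in.sum() * col_in.sum() < 100:
        raise DataError("ROI clipped to the image retains fewer than 100 pixels")
    sub = image.pixels[np.ix_(row_in, col_in)]
    Y, X = np.meshgrid(ys[row_in], xs[col_in], indexing="ij")
    r2 = (Y - cy) ** 2 + (X - cx) ** 2
    if signal_radius is None:
        s_max = float(sub.max())
    else:
        sig = r2 <= signal_radius**2
        if not sig.any():
            raise DataError("signal_radius selects no pixels")
        s_max = float(sub[sig].max())
    keep = r2 > exclusion_radius**2
    for ey, ex in exclude_centers or ():
        keep &= (Y - ey) ** 2 + (X - ex) ** 2 > exclusion_radius**2
    bg = sub[keep]
    if bg.size < 2:
        raise DataError("background region is degenerate")
    return ROIStats(
        s_max=s_max,
        s_bg_mean=float(bg.mean()),
        s_bg_sd=float(bg.std(ddof=1)),
        n_bg=int(bg.size),
    )


def compute_cnr(stats: ROIStats) -> float:
    """Contrast-to-noise ratio ``(S_max - S_bg_mean) / S_bg_sd``.

    Invariant under positive affine intensity rescaling. Raises
    :class:`UndefinedCNRError` for zero background SD (noise-free synthetic
    input; enable noise in the protocol).
    """
    if stats.s_bg_sd == 0:
        raise UndefinedCNRError(
            "background SD is zero, CNR undefined (noise-free synthetic image?)"
        )
    return (stats.s_max - stats.s_bg_mean) / stats.s_bg_sd


def ring_artifact_profile(
    image: Image2D,
    center: tuple[float, float],
    r_min: float = 1.0,
    r_max: float = 15.0,
    n_rings: int = 1000,
    n_angular: int = 720,
) -> RingProfile:
    """SD of bilinearly interpolated intensities along ``n_rings`` rings.

    Radii are uniformly spaced and inclusive of both ``r_min`` and
    ``r_max``; each ring is sampled at ``n_angular`` equally spaced angles.
    Rings must lie fully inside the image.
    """
    if n_rings < 2:
        raise GeometryError("need at least 2 rings")
    if not (0 < r_min < r_max):
        raise GeometryError("require 0 < r_min < r_max")
    cy, cx = center
    radii = np.linspace(r_min, r_max, n_rings)
    ny, nx = image.shape
    y_lo, x_lo = image.index_to_phys(0, 0)
    y_hi, x_hi = image.index_to_phys(ny - 1, nx - 1)
    for r in (r_min, r_max):
        if cy - r < y_lo or cy + r > y_hi or cx - r < x_lo or cx + r > x_hi:
            raise GeometryError(f"ring of radius {r} mm exits the image")
    theta = 2.0 * np.pi * np.arange(n_angular) / n_angular
    ct, st = np.cos(theta), np.sin(theta)
    ys = cy + radii[:, None] * st[None, :]
    xs = cx + radii[:, None] * ct[None, :]
    samples = image.interp(ys, xs)
    sd = samples.std(axis=1, ddof=1)
    return RingProfile(radii=radii, sd_per_ring=sd, center=(float(cy), float(cx)))


def artifact_index(profile: RingProfile) -> float:
    """Scalar artifact summary: mean of the per-ring SDs (zero iff all zero)."""
    return float(np.mean(profile.sd_per_ring))
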