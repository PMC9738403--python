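"""Point-pattern statistics for facility and station distributions.

Implements the four descriptive procedures used to characterise the spatial
layout of medical facilities and transit stops in a projected metric frame:

* the nearest-neighbor ratio (Clark–Evans R) with its aggregation /
  random / uniform classification,
* quartic (biweight) kernel density surfaces on a raster grid,
* the mean center, and
* the standard deviational ellipse (SDE) from the 1/n coordinate
  covariance matrix.

All coordinates are planar meters; areas are m². No edge correction is
applied to the nearest-neighbor statistic (the plain Clark–Evans form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointPattern",
    "NNResult",
    "KDEGrid",
    "DeviationalEllipse",
    "InsufficientPointsError",
    "mean_nn_distance",
    "expected_nn_distance",
    "nn_ratio",
    "nn_analysis",
    "kernel_density",
    "mean_center",
    "standard_deviational_ellipse",
]


class InsufficientPointsError(ValueError):
    """A pattern has too few points for the requested statistic."""


@dataclass(frozen=True)
class PointPattern:
    """A labeled set of points in a projected metric coordinate system.

    Parameters
    ----------
    points
        Array-like of shape (n, 2), x/y in meters.
    label
        Facility class or station mode the points belong to.
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class NNResult:
    """Nearest-neighbor analysis summary.

    ``R = r1bar / rebar`` where ``r1bar`` is the observed mean
    nearest-neighbor distance and ``rebar = 0.5 * sqrt(A / n)`` the
    expectation under complete spatial randomness on area ``A``.
    """

    r1bar: float
    rebar: float
    R: float
    A: float
    n: int
    classification: str  # "aggregation" | "random" | "uniform"


@dataclass(frozen=True)
class KDEGrid:
    """Quartic kernel density surface sampled at raster cell centers."""

    origin: tuple[float, float]  # lower-left corner (x, y), meters
    cell_size: float
    values: np.ndarray  # shape (ny, nx), row 0 = southernmost, per m²
    radius: float

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return cx, cy

    def total_mass(self) -> float:
        """Integral of the surface (Σ values · cell area); ≈ n for interior patterns."""
        return float(self.values.sum() * self.cell_size**2)


@dataclass(frozen=True)
class DeviationalEllipse:
    """Standard deviational ellipse of a point pattern.

    ``covariance`` is the population (1/n) covariance matrix of the
    centered coordinates; ``sigma_major``/``sigma_minor`` are the square
    roots of its eigenvalues and ``rotation`` the counter-clockwise angle
    of the major axis from east, in [0, π).
    """

    center: tuple[float, float]
    sigma_major: float
    sigma_minor: float
    rotation: float
    covariance: np.ndarray
    degenerate: bool = field(default=False)


def mean_nn_distance(pattern: PointPattern) -> float:
    """Mean distance from each point to its nearest other point (r1̄).

    Coincident duplicates contribute distance 0 with a warning; fewer
    than two points is an error.
    """
    if pattern.n < 2:
        raise InsufficientPointsError("nearest-neighbor distance needs n >= 2")
    tree = cKDTree(pattern.points)
    dists, _ = tree.query(pattern.points, k=2)
    nn = dists[:, 1]
    if np.any(nn == 0):
        warnings.warn(
            "coincident duplicate points: zero nearest-neighbor distances",
            stacklevel=2,
        )
    return float(nn.mean())


def expected_nn_distance(n: int, A: float) -> float:
    """Expected mean nearest-neighbor distance under CSR: 0.5·√(A/n)."""
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if A <= 0:
        raise ValueError(f"area must be positive, got {A}")
    return 0.5 * float(np.sqrt(A / n))


def nn_ratio(r1bar: float, rebar: float, tol: float = 0.01) -> tuple[float, str]:
    """Nearest-neighbor ratio R = r1̄ / rε̄ and its classification.

    R < 1 − tol → "aggregation" (clustered), R > 1 + tol → "uniform"
    (dispersed), otherwise "random".
    """
    if rebar <= 0:
        raise ValueError(f"expected distance must be positive, got {rebar}")
    R = r1bar / rebar
    if R < 1.0 - tol:
        cls = "aggregation"
    elif R > 1.0 + tol:
        cls = "uniform"
    else:
        cls = "random"
    return float(R), cls


def nn_analysis(pattern: PointPattern, A: float, tol: float = 0.01) -> NNResult:
    """Full nearest-neighbor analysis of a pattern on study area ``A`` (m²)."""
    r1bar = mean_nn_distance(pattern)
    rebar = expected_nn_distance(pattern.n, A)
    R, cls = nn_ratio(r1bar, rebar, tol=tol)
    return NNResult(r1bar=r1bar, rebar=rebar, R=R, A=float(A), n=pattern.n, classification=cls)


def kernel_density(
    pattern: PointPattern,
    radius: float,
    cell_size: float,
    extent: tuple[float, float, float, float],
) -> KDEGrid:
    """Quartic kernel density surface of a point pattern.

    The value at a cell center c is::

        D(c) = Σ_p  3 (1 − (d/r)²)² / (π r²)   over points p with d = |c−p| < r

    so each point's kernel integrates to 1 and the surface has units of
    points per m². ``extent`` is (xmin, ymin, xmax, ymax); the grid
    covers it with square cells of ``cell_size``, evaluated at centers.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if radius <= cell_size:
        warnings.warn(
            f"search radius {radius} <= cell size {cell_size}: undersampled kernel",
            stacklevel=2,
        )
    xmin, ymin, xmax, ymax = extent
    nx = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    values = np.zeros((ny, nx))
    cx = xmin + (np.arange(nx) + 0.5) * cell_size
    cy = ymin + (np.arange(ny) + 0.5) * cell_size
    norm = 3.0 / (np.pi * radius**2)
    # per-point local window keeps this O(n · (r/cell)²) instead of O(n · cells)
    for px, py in pattern.points:
        i0 = max(0, int((px - radius - xmin) / cell_size))
        i1 = min(nx, int((px + radius - xmin) / cell_size) + 1)
        j0 = max(0, int((py - radius - ymin) / cell_size))
        j1 = min(ny, int((py + radius - ymin) / cell_size) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = cx[i0:i1] - px
        dy = cy[j0:j1] - py
        d2 = dx[None, :] ** 2 + dy[:, None] ** 2
        u2 = d2 / radius**2
        inside = u2 < 1.0
        values[j0:j1, i0:i1] += np.where(inside, norm * (1.0 - u2) ** 2, 0.0)
    return KDEGrid(origin=(xmin, ymin), cell_size=float(cell_size), values=values, radius=float(radius))


def mean_center(pattern: PointPattern) -> tuple[float, float]:
    """Arithmetic mean of the x and y coordinates (the geographic center)."""
    if pattern.n < 1:
        raise InsufficientPointsError("mean center needs at least one point")
    return float(pattern.x.mean()), float(pattern.y.mean())


def standard_deviational_ellipse(pattern: PointPattern) -> DeviationalEllipse:
    """Standard deviational ellipse from the 1/n coordinate covariance.

    The axes are the square roots of the eigenvalues of::

        C = (1/n) Σ [x̃ᵢ², x̃ᵢỹᵢ; x̃ᵢỹᵢ, ỹᵢ²],    x̃ᵢ = xᵢ − x̄

    (population normalization; one standard deviation, no rendering
    scale factor). Collinear patterns return ``sigma_minor = 0`` with
    ``degenerate=True`` rather than raising.
    """
    if pattern.n < 3:
        raise InsufficientPointsError("deviational ellipse needs n >= 3")
    cx, cy = mean_center(pattern)
    xt = pattern.x - cx
    yt = pattern.y - cy
    C = np.array(
        [
            [np.mean(xt * xt), np.mean(xt * yt)],
            [np.mean(xt * yt), np.mean(yt * yt)],
        ]
    )
    evals, evecs = np.linalg.eigh(C)  # ascending
    evals = np.clip(evals, 0.0, None)
    sigma_minor, sigma_major = float(np.sqrt(evals[0])), float(np.sqrt(evals[1]))
    major_vec = evecs[:, 1]
    rotation = float(np.arctan2(major_vec[1], major_vec[0])) % np.pi
    degenerate = bool(np.isclose(sigma_minor, 0.0, atol=1e-12 * max(sigma_major, 1.0)))
    return DeviationalEllipse(
        center=(cx, cy),
        sigma_major=sigma_major,
        sigma_minor=sigma_minor,
        rotation=rotation,
        covariance=C,
        degenerate=degenerate,
    )
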