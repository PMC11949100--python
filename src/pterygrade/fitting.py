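"""Contour extraction and robust circle reconstruction.

After segmentation the visible cornea (or pupil) is an incomplete disc:
the pterygium occludes part of it, so the extracted boundary mixes true
limbal-arc points with leading-edge points that are outliers with respect
to the underlying circle.  Ordinary least squares is pulled toward those
outliers; iteratively reweighted least squares (IRLS) with a Huber or
Tukey weight progressively down-weights them and recovers the full circle.

Conventions: coordinates are 0-based with ``x`` the column and ``y`` the
row; pixel centres sit at integer coordinates.  Residuals are signed
geometric residuals ``||p - c|| - r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage

from .phantom import LabelMask

# 95%-efficiency tuning constants for the scale-adaptive gamma policy
HUBER_K = 1.345
TUKEY_K = 4.685
_MAD_TO_SIGMA = 1.0 / 0.6745
# during the first ~60% of iterations the residual-scale estimate is forced
# to decay geometrically; without this the MAD stays inflated by the biased
# initial fit when a long dense arc is occluded, and the reweighting stalls
_ANNEAL_DECAY = 0.7
_ANNEAL_FRACTION = 0.6


class EmptyClassError(ValueError):
    """Raised when a requested class has no pixels in the mask."""


class DegenerateGeometryError(ValueError):
    """Raised when a circle cannot be determined (too few / collinear points)."""


class WeightCollapseError(RuntimeError):
    """Raised when the robust weights reject essentially every point."""


@dataclass(frozen=True)
class ContourPointSet:
    """Ordered outer-boundary pixels of one class region.

    Points follow a clockwise boundary trace starting from the
    topmost-then-leftmost boundary pixel of the largest 8-connected
    component.
    """

    points: np.ndarray  # (N, 2) float array of (x, y)
    source_class: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (N, 2) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class WeightFunctionSpec:
    """Choice of M-estimation weight and its gamma policy.

    ``gamma_policy`` is either a fixed positive cutoff or ``"auto"``, in
    which case gamma is re-estimated each iteration from the residual
    scale (median absolute deviation scaled to the normal) times the
    weight function's 95%-efficiency constant.
    """

    kind: str = "tukey"
    gamma_policy: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "huber", "tukey"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if isinstance(self.gamma_policy, str):
            if self.gamma_policy != "auto":
                raise ValueError("gamma_policy must be a positive number or 'auto'")
        elif self.gamma_policy <= 0:
            raise ValueError("fixed gamma must be positive")


@dataclass(frozen=True)
class CircleFit:
    """A fitted circle with per-point diagnostics."""

    center: tuple[float, float]
    radius: float
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


# Moore neighbourhood in clockwise order starting from north, as (dy, dx)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(region: np.ndarray) -> list[tuple[int, int]]:
    """Clockwise Moore-neighbour boundary trace of a connected region.

    Returns (y, x) pixels in trace order, starting from the
    topmost-then-leftmost region pixel; Jacob's stopping criterion ends
    the walk when the start pixel is re-entered from the same direction.
    """
    ys, xs = np.nonzero(region)
    start = (int(ys.min()), int(xs[ys == ys.min()].min()))

    H, W = region.shape

    def inside(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < H and 0 <= p[1] < W and region[p]

    # direction index pointing back toward the previous (outside) pixel;
    # the start pixel is topmost, so "north" is guaranteed outside
    trace = [start]
    current = start
    backtrack_dir = 0
    first_move: tuple[int, int, int] | None = None
    for _ in range(4 * region.size):  # safety bound, never hit in practice
        found = False
        for step in range(1, 9):
            d = (backtrack_dir + step) % 8
            nxt = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if inside(nxt):
                move = (current[0], current[1], d)
                if first_move is None:
                    first_move = move
                elif move == first_move:
                    return trace
                trace.append(nxt)
                # backtrack from the new pixel toward the neighbour
                # scanned (and rejected) just before the accepted one
                prev_reject = (
                    current[0] + _MOORE[(d - 1) % 8][0],
                    current[1] + _MOORE[(d - 1) % 8][1],
                )
                dy = prev_reject[0] - nxt[0]
                dx = prev_reject[1] - nxt[1]
                backtrack_dir = _MOORE.index((dy, dx))
                current = nxt
                found = True
                break
        if not found:  # isolated pixel
            return trace
    return trace


def extract_class_contour(mask: LabelMask, class_code: int) -> ContourPointSet:
    """Outer boundary of the largest 8-connected component of a class.

    The trace is deterministic: clockwise from the topmost-then-leftmost
    boundary pixel.  Smaller islands of the class are treated as
    segmentation noise and ignored.
    """
    binary = np.asarray(mask) == class_code
    if not binary.any():
        raise EmptyClassError(f"mask contains no pixels of class {class_code}")
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(binary, structure=structure)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = int(np.argmax(sizes))  # ties -> lowest label, deterministic
        component = labels == keep
    else:
        component = binary
    pixels = _trace_boundary(component)
    seen: set[tuple[int, int]] = set()
    pts = []
    for y, x in pixels:
        if (y, x) not in seen:
            seen.add((y, x))
            pts.append((float(x), float(y)))
    return ContourPointSet(points=np.array(pts), source_class=int(class_code))


def weight_value(spec: WeightFunctionSpec, delta, gamma: float):
    """Evaluate the weight function at residual(s) ``delta``.

    Huber: 1 for |delta| <= gamma, gamma/|delta| beyond.  Tukey biweight:
    (1 - (|delta|/gamma)^2)^2 inside the cutoff, 0 beyond.  Uniform: 1.
    Accepts scalars or arrays; returns the matching shape.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = np.abs(np.asarray(delta, dtype=float))
    if spec.kind == "uniform":
        w = np.ones_like(a)
    elif spec.kind == "huber":
        w = np.where(a <= gamma, 1.0, gamma / np.maximum(a, gamma))
    else:  # tukey
        w = np.where(a <= gamma, (1.0 - (a / gamma) ** 2) ** 2, 0.0)
    if np.isscalar(delta) or np.asarray(delta).ndim == 0:
        return float(w)
    return w


def _solve_kasa(points: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted algebraic (Kasa) circle solve.

    Linearises x^2 + y^2 + a x + b y + c = 0; the diagonal weight matrix
    enters as sqrt(w) row scaling of the least-squares system.
    """
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x * x + y * y)
    sw = np.sqrt(weights)[:, None]
    sol, _, rank, _ = np.linalg.lstsq(A * sw, (b.ravel() * sw.ravel()), rcond=None)
    if rank < 3:
        raise DegenerateGeometryError("points are collinear or too few for a circle")
    a, bb, c = sol
    cx, cy = -a / 2.0, -bb / 2.0
    r2 = cx * cx + cy * cy - c
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate circle (non-positive radius)")
    return float(cx), float(cy), float(np.sqrt(r2))


def _residuals(points: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    return np.hypot(points[:, 0] - cx, points[:, 1] - cy) - r


def fit_circle_algebraic(points: ContourPointSet | np.ndarray,
                         weights: np.ndarray | None = None) -> CircleFit:
    """Single algebraic least-squares circle fit (IRLS initialisation)."""
    pts = points.points if isinstance(points, ContourPointSet) else np.asarray(points, float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to fit a circle")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    cx, cy, r = _solve_kasa(pts, w)
    return CircleFit(center=(cx, cy), radius=r, weights=w,
                     residuals=_residuals(pts, cx, cy, r),
                     n_iterations=1, converged=True)


def fit_circle_irls(points: ContourPointSet | np.ndarray,
                    spec: WeightFunctionSpec = WeightFunctionSpec(),
                    max_iterations: int = 10,
                    tolerance: float = 1e-6) -> CircleFit:
    """Robust circle fit by iteratively reweighted least squares.

    Alternates a weighted algebraic solve, a residual update and a weight
    update until the centre-plus-radius change drops below ``tolerance``
    or ``max_iterations`` is reached (default 10).  With the ``uniform``
    weight this reduces exactly to :func:`fit_circle_algebraic`.
    """
    pts = points.points if isinstance(points, ContourPointSet) else np.asarray(points, float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points to fit a circle")

    fit = fit_circle_algebraic(pts)
    if spec.kind == "uniform":
        return fit

    cx, cy = fit.center
    r = fit.radius
    w = fit.weights
    delta = fit.residuals
    converged = False
    n_done = 1
    s_env = np.inf
    n_anneal = int(np.ceil(_ANNEAL_FRACTION * max_iterations))
    for it in range(1, max_iterations):
        if spec.gamma_policy == "auto":
            mad = np.median(np.abs(delta - np.median(delta)))
            s = mad * _MAD_TO_SIGMA
            if it <= n_anneal:
                s = min(s, _ANNEAL_DECAY * s_env)
            s_env = s
            if s <= tolerance:  # residual scale ~0: fit is already exact
                converged = True
                break
            k = HUBER_K if spec.kind == "huber" else TUKEY_K
            gamma = k * s
        else:
            gamma = float(spec.gamma_policy)
        w = weight_value(spec, delta, gamma)
        total = float(np.sum(w))
        if total < 3.0 * 1e-8 or np.count_nonzero(w) < 3:
            raise WeightCollapseError(
                "robust weights rejected nearly all points; increase gamma")
        ncx, ncy, nr = _solve_kasa(pts, w)
        delta = _residuals(pts, ncx, ncy, nr)
        change = abs(ncx - cx) + abs(ncy - cy) + abs(nr - r)
        cx, cy, r = ncx, ncy, nr
        n_done = it + 1
        if change < tolerance:
            converged = True
            break
    return CircleFit(center=(cx, cy), radius=r, weights=np.asarray(w, float),
                     residuals=delta, n_iterations=n_done, converged=converged)
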