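"""Pair correlation statistics for labelled point clouds.

Implements the cross-type pair correlation function (cross-PCF) with an
exact annulus border correction, and its generalisation to continuous
marks, the weighted pair correlation function (wPCF).

The cross-PCF between a source category Q and a target category Q' is

    g_QQ'(r_k) = (1 / (N_Q N_Q')) sum_i sum_j (A / A_rk(x_i))
                 Theta(Q, q_i) Theta(Q', q_j) I_k(|x_i - x_j|),

where annuli [r_k, r_k + dr) are centred on *source* points, targets are
counted, A is the domain area and A_rk(x_i) the area of the annulus around
x_i that lies inside the domain.  A value of 1 in a bin means the target
density at that distance from sources matches the density expected under
complete spatial randomness; >1 means clustering, <1 exclusion.

The wPCF replaces the source indicator by a weight w_p(P, p_i) in [0, 1]
measuring how close the continuous mark p_i is to a target mark P, and the
source count by the total weight W_P = sum_i w_p(P, p_i):

    wPCF(r_k, P, Q') = (1 / (W_P N_Q')) sum_i sum_j (A / A_rk(x_i))
                       w_p(P, p_i) Theta(Q', q_j) I_k(|x_i - x_j|).

Annuli are centred on the mark-carrying points.  Rows of the (P, r) surface
with W_P = 0 are undefined and reported as NaN with an explicit mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pointcloud import Domain, LabelledPointCloud

__all__ = [
    "RadialBinning",
    "WeightingSpec",
    "CrossPCFResult",
    "WPCFSurface",
    "annulus_area",
    "circle_rectangle_area",
    "cross_pcf",
    "default_P_grid",
    "weight",
    "wpcf",
    "wpcf_slice",
    "wpcf_two_marks",
]


@dataclass(frozen=True)
class RadialBinning:
    """Contiguous half-open annular bins [r_k, r_k + dr), r_k = k dr.

    Defaults (dr = 0.1 cell diameters, 191 bins, r in [0, 19.1)) cover the
    0-20 cell-diameter range over which tumour-scale spatial structure
    (perivascular niches, exclusion zones) is expressed.
    """

    dr: float = 0.1
    n_bins: int = 191

    def __post_init__(self) -> None:
        if self.dr <= 0:
            raise ValueError("dr must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")

    @property
    def inner_radii(self) -> np.ndarray:
        return self.dr * np.arange(self.n_bins)

    @property
    def edges(self) -> np.ndarray:
        return self.dr * np.arange(self.n_bins + 1)

    @property
    def r_max(self) -> float:
        return self.dr * self.n_bins


@dataclass(frozen=True)
class WeightingSpec:
    """How a mark p is compared with a target mark P.

    kind
        ``triangular`` (default): w = max(1 - |P - p| / delta_P, 0).
        ``gaussian``: w = exp(-(P - p)^2 / (2 delta_P^2)), a smooth
        alternative with unbounded support.
        ``indicator``: w = 1 when |P - p| <= delta_P else 0; the
        delta_P -> 0 limit of the triangular kernel, which reduces each
        wPCF row to the cross-PCF of the exactly-matching sub-population.
    delta_P
        Kernel width: triangular half-width, gaussian standard deviation,
        or indicator match tolerance.  The default 0.2 trades phenotype
        resolution against estimator noise.
    """

    kind: str = "triangular"
    delta_P: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("triangular", "gaussian", "indicator"):
            raise ValueError(f"unknown weighting kind {self.kind!r}")
        if self.kind == "indicator":
            if self.delta_P < 0:
                raise ValueError("indicator tolerance must be >= 0")
        elif self.delta_P <= 0:
            raise ValueError("delta_P must be positive")


def weight(spec: WeightingSpec, P, p) -> np.ndarray:
    """Evaluate w_p(P, p) for scalar or array arguments (broadcasting)."""
    P = np.asarray(P, dtype=float)
    p = np.asarray(p, dtype=float)
    d = np.abs(P - p)
    if spec.kind == "triangular":
        return np.maximum(1.0 - d / spec.delta_P, 0.0)
    if spec.kind == "gaussian":
        return np.exp(-0.5 * (d / spec.delta_P) ** 2)
    return (d <= spec.delta_P).astype(float)


@dataclass
class CrossPCFResult:
    """One cross-PCF curve g(r) over a radial binning.

    ``values`` is all-NaN (undefined) when either population is empty.
    """

    binning: RadialBinning
    values: np.ndarray
    source_category: str
    target_category: str
    n_source: int
    n_target: int

    @property
    def radii(self) -> np.ndarray:
        return self.binning.inner_radii

    @property
    def is_defined(self) -> bool:
        return self.n_source > 0 and self.n_target > 0


@dataclass
class WPCFSurface:
    """wPCF values over a (P, r) grid.

    ``values[m, k]`` is wPCF(r_k, P_grid[m], target); rows where the total
    weight W_P is zero are NaN and flagged in ``undefined_mask``.
    """

    binning: RadialBinning
    P_grid: np.ndarray
    values: np.ndarray
    total_weight: np.ndarray
    target_category: str
    n_target: int = 0
    undefined_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.P_grid = np.asarray(self.P_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.total_weight = np.asarray(self.total_weight, dtype=float)
        if self.undefined_mask is None:
            self.undefined_mask = self.total_weight == 0
        if self.values.shape != (len(self.P_grid), self.binning.n_bins):
            raise ValueError("values shape does not match (P_grid, binning)")

    @property
    def radii(self) -> np.ndarray:
        return self.binning.inner_radii


def default_P_grid(n: int = 101) -> np.ndarray:
    """Evenly spaced target marks covering [0, 1] (default 0, 0.01, ..., 1)."""
    return np.linspace(0.0, 1.0, n)


# ---------------------------------------------------------------------------
# annulus geometry with border correction


def _quadrant_area(a: np.ndarray, b: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Area of circle(origin, R) ∩ rectangle [0, a] x [0, b], a, b >= 0."""
    a = np.minimum(a, R)
    b = np.minimum(b, R)
    with np.errstate(invalid="ignore", divide="ignore"):
        inside = a * a + b * b <= R * R
        xb = np.sqrt(np.maximum(R * R - b * b, 0.0))
        # F(x) = int_0^x sqrt(R^2 - t^2) dt
        ratio_a = np.where(R > 0, np.clip(a / np.where(R > 0, R, 1.0), 0, 1), 0.0)
        ratio_xb = np.where(R > 0, np.clip(xb / np.where(R > 0, R, 1.0), 0, 1), 0.0)
        F_a = 0.5 * (a * np.sqrt(np.maximum(R * R - a * a, 0.0)) + R * R * np.arcsin(ratio_a))
        F_xb = 0.5 * (xb * b + R * R * np.arcsin(ratio_xb))
        curved = b * xb + F_a - F_xb
    return np.where(R <= 0, 0.0, np.where(inside, a * b, curved))


def _signed_quadrant(a: np.ndarray, b: np.ndarray, R: np.ndarray) -> np.ndarray:
    return np.sign(a) * np.sign(b) * _quadrant_area(np.abs(a), np.abs(b), R)


def circle_rectangle_area(
    centers: np.ndarray, radii: np.ndarray, domain: Domain
) -> np.ndarray:
    """Exact area of circle ∩ domain rectangle, broadcasting centers x radii.

    ``centers`` is (n, 2); ``radii`` broadcasts against shape (n, ...).
    Uses the signed corner decomposition of the circle-rectangle overlap.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float)
    if radii.ndim == 0:
        radii = np.full(len(centers), float(radii))
    if radii.ndim == 1:
        cx, cy = centers[:, 0], centers[:, 1]
    elif radii.ndim == 2 and radii.shape[0] == len(centers):
        cx, cy = centers[:, 0][:, None], centers[:, 1][:, None]
    else:
        raise ValueError("radii must have shape (n,) or (n, m) for n centers")
    a1 = domain.x_max - cx
    a0 = domain.x_min - cx
    b1 = domain.y_max - cy
    b0 = domain.y_min - cy
    return (
        _signed_quadrant(a1, b1, radii)
        - _signed_quadrant(a0, b1, radii)
        - _signed_quadrant(a1, b0, radii)
        + _signed_quadrant(a0, b0, radii)
    )


def annulus_area(center, r_k: float, dr: float, domain: Domain) -> float:
    """Area of the annulus [r_k, r_k + dr) around ``center`` inside the domain.

    For a periodic domain this is always the full ring area pi (2 r_k + dr) dr;
    for a clipped domain the ring is intersected with the rectangle (the
    border correction used throughout the statistics).
    """
    if r_k < 0 or dr <= 0:
        raise ValueError("need r_k >= 0 and dr > 0")
    center = np.asarray(center, dtype=float).reshape(2)
    if not domain.contains(center[None, :])[0]:
        raise ValueError("annulus center lies outside the domain")
    if domain.boundary_mode == "periodic":
        return np.pi * (2 * r_k + dr) * dr
    outer = circle_rectangle_area(center[None, :], np.array([r_k + dr]), domain)
    inner = circle_rectangle_area(center[None, :], np.array([r_k]), domain)
    return float(outer[0] - inner[0])


def _annulus_area_matrix(
    centers: np.ndarray, binning: RadialBinning, domain: Domain
) -> np.ndarray:
    """(n_centers, n_bins) border-corrected annulus areas."""
    if domain.boundary_mode == "periodic":
        ring = np.pi * (2 * binning.inner_radii + binning.dr) * binning.dr
        return np.broadcast_to(ring, (len(centers), binning.n_bins)).copy()
    edges = binning.edges  # (n_bins + 1,)
    disc = circle_rectangle_area(centers, np.broadcast_to(edges, (len(centers), len(edges))), domain)
    return np.diff(disc, axis=1)


def _pairwise_distances(a: np.ndarray, b: np.ndarray, domain: Domain) -> np.ndarray:
    dx = np.abs(a[:, 0][:, None] - b[:, 0][None, :])
    dy = np.abs(a[:, 1][:, None] - b[:, 1][None, :])
    if domain.boundary_mode == "periodic":
        dx = np.minimum(dx, domain.width - dx)
        dy = np.minimum(dy, domain.height - dy)
    return np.hypot(dx, dy)


def _binned_counts(
    centers: np.ndarray,
    points: np.ndarray,
    binning: RadialBinning,
    domain: Domain,
    exclude_diagonal: bool = False,
    point_weights: np.ndarray | None = None,
) -> np.ndarray:
    """(n_centers, n_bins) counts (or weighted counts) of points per annulus."""
    n_c = len(centers)
    out = np.zeros((n_c, binning.n_bins))
    if n_c == 0 or len(points) == 0:
        return out
    d = _pairwise_distances(centers, points, domain)
    if exclude_diagonal:
        np.fill_diagonal(d, np.inf)
    valid = np.isfinite(d) & (d < binning.r_max)
    ci, pj = np.nonzero(valid)
    k = (d[ci, pj] / binning.dr).astype(np.int64)
    w = np.ones(len(ci)) if point_weights is None else point_weights[pj]
    np.add.at(out, (ci, k), w)
    return out


def _contributions(
    centers: np.ndarray,
    points: np.ndarray,
    binning: RadialBinning,
    domain: Domain,
    exclude_diagonal: bool = False,
) -> np.ndarray:
    """Per-centre, per-bin term A * count / A_rk; zero where the ring has no area."""
    counts = _binned_counts(centers, points, binning, domain, exclude_diagonal)
    areas = _annulus_area_matrix(centers, binning, domain)
    out = np.zeros_like(counts)
    ok = areas > 0
    out[ok] = domain.area * counts[ok] / areas[ok]
    return out


# ---------------------------------------------------------------------------
# public statistics


def cross_pcf(
    cloud: LabelledPointCloud,
    source: str,
    target: str,
    binning: RadialBinning | None = None,
) -> CrossPCFResult:
    """Cross-PCF with annuli centred on ``source`` points, counting ``target``.

    Self-pairs are excluded when source == target.  When either population
    is empty the result is flagged undefined (all-NaN values), not raised.
    """
    binning = binning or RadialBinning()
    src = cloud.positions[cloud.category_mask(source)]
    tgt = cloud.positions[cloud.category_mask(target)]
    n_s, n_t = len(src), len(tgt)
    if n_s == 0 or n_t == 0:
        return CrossPCFResult(
            binning, np.full(binning.n_bins, np.nan), source, target, n_s, n_t
        )
    contrib = _contributions(
        src, tgt, binning, cloud.domain, exclude_diagonal=(source == target)
    )
    values = contrib.sum(axis=0) / (n_s * n_t)
    return CrossPCFResult(binning, values, source, target, n_s, n_t)


def wpcf(
    cloud: LabelledPointCloud,
    target: str,
    binning: RadialBinning | None = None,
    P_grid: np.ndarray | None = None,
    spec: WeightingSpec | None = None,
) -> WPCFSurface:
    """Weighted PCF between mark-carrying points and a categorical target.

    Annuli are centred on every point with a defined (non-NaN) mark -- in
    tumour snapshots, the macrophages, weighted by how close their phenotype
    is to each target mark P.  Rows with total weight W_P = 0 are NaN.
    """
    binning = binning or RadialBinning()
    P_grid = default_P_grid() if P_grid is None else np.asarray(P_grid, dtype=float)
    spec = spec or WeightingSpec()
    carriers = ~np.isnan(cloud.marks)
    marks = cloud.marks[carriers]
    centers = cloud.positions[carriers]
    tgt_mask = cloud.category_mask(target)
    tgt = cloud.positions[tgt_mask]
    n_t = len(tgt)

    n_P = len(P_grid)
    if len(centers) == 0 or n_t == 0:
        if len(centers) == 0:
            warnings.warn("no mark-carrying points: wPCF surface is fully undefined")
        return WPCFSurface(
            binning,
            P_grid,
            np.full((n_P, binning.n_bins), np.nan),
            np.zeros(n_P),
            target,
            n_t,
            np.ones(n_P, dtype=bool),
        )

    # a mark carrier that is itself a target point must not count itself
    same = carriers & tgt_mask
    if same.any():
        d = _pairwise_distances(centers, tgt, cloud.domain)
        carrier_idx = np.flatnonzero(carriers)
        target_idx = np.flatnonzero(tgt_mask)
        ci = np.searchsorted(carrier_idx, np.flatnonzero(same))
        tj = np.searchsorted(target_idx, np.flatnonzero(same))
        d[ci, tj] = np.inf
        counts = np.zeros((len(centers), binning.n_bins))
        valid = np.isfinite(d) & (d < binning.r_max)
        ii, jj = np.nonzero(valid)
        k = (d[ii, jj] / binning.dr).astype(np.int64)
        np.add.at(counts, (ii, k), 1.0)
        areas = _annulus_area_matrix(centers, binning, cloud.domain)
        contrib = np.zeros_like(counts)
        ok = areas > 0
        contrib[ok] = cloud.domain.area * counts[ok] / areas[ok]
    else:
        contrib = _contributions(centers, tgt, binning, cloud.domain)

    W = weight(spec, P_grid[:, None], marks[None, :])  # (n_P, n_carriers)
    total_weight = W.sum(axis=1)
    values = W @ contrib  # (n_P, n_bins)
    defined = total_weight > 0
    values[defined] /= total_weight[defined, None] * n_t
    values[~defined] = np.nan
    return WPCFSurface(binning, P_grid, values, total_weight, target, n_t, ~defined)


def wpcf_slice(
    surface: WPCFSurface, P: float, interpolate: bool = False
) -> CrossPCFResult:
    """One horizontal slice wPCF(r, P=const), interpretable as a cross-PCF
    between points whose marks are close to P and the target category.

    By default P must match a grid value exactly; with ``interpolate=True``
    the nearest grid row is returned.
    """
    diffs = np.abs(surface.P_grid - P)
    idx = int(np.argmin(diffs))
    if not interpolate and diffs[idx] > 1e-9:
        raise ValueError(f"P={P} is not on the surface's mark grid")
    return CrossPCFResult(
        binning=surface.binning,
        values=surface.values[idx].copy(),
        source_category=f"mark~{surface.P_grid[idx]:g}",
        target_category=surface.target_category,
        n_source=int(round(surface.total_weight[idx])),
        n_target=surface.n_target,
    )


def wpcf_two_marks(
    cloud_a: LabelledPointCloud,
    cloud_b: LabelledPointCloud,
    binning: RadialBinning | None = None,
    P1_grid: np.ndarray | None = None,
    P2_grid: np.ndarray | None = None,
    spec: WeightingSpec | None = None,
) -> np.ndarray:
    """wPCF between two mark-carrying populations, over (P1, P2, r).

    Annuli are centred on cloud_a's mark carriers weighted by w(P1, .);
    cloud_b's mark carriers are counted with weight w(P2, .); each (P1, P2)
    layer is normalised by W_P1 W_P2 / A.  Entries where either total
    weight vanishes are NaN.  Both clouds must share a domain.
    """
    binning = binning or RadialBinning()
    P1_grid = default_P_grid() if P1_grid is None else np.asarray(P1_grid, dtype=float)
    P2_grid = default_P_grid() if P2_grid is None else np.asarray(P2_grid, dtype=float)
    spec = spec or WeightingSpec()
    if cloud_a.domain.to_dict() != cloud_b.domain.to_dict():
        raise ValueError("the two clouds must share a domain")
    domain = cloud_a.domain

    ca = ~np.isnan(cloud_a.marks)
    cb = ~np.isnan(cloud_b.marks)
    pos_a, marks_a = cloud_a.positions[ca], cloud_a.marks[ca]
    pos_b, marks_b = cloud_b.positions[cb], cloud_b.marks[cb]
    out = np.full((len(P1_grid), len(P2_grid), binning.n_bins), np.nan)
    W1 = weight(spec, P1_grid[:, None], marks_a[None, :]) if len(pos_a) else np.zeros((len(P1_grid), 0))
    W2 = weight(spec, P2_grid[:, None], marks_b[None, :]) if len(pos_b) else np.zeros((len(P2_grid), 0))
    tw1 = W1.sum(axis=1)
    tw2 = W2.sum(axis=1)
    if len(pos_a) == 0 or len(pos_b) == 0:
        return out

    d = _pairwise_distances(pos_a, pos_b, domain)
    if cloud_a is cloud_b:
        np.fill_diagonal(d, np.inf)
    valid = np.isfinite(d) & (d < binning.r_max)
    areas = _annulus_area_matrix(pos_a, binning, domain)
    inv_area = np.zeros_like(areas)
    inv_area[areas > 0] = domain.area / areas[areas > 0]
    ii, jj = np.nonzero(valid)
    kk = (d[ii, jj] / binning.dr).astype(np.int64)
    # accumulate sum_ij w1(P1,i) w2(P2,j) A / A_rk(x_i) per bin
    for m2, w2_row in enumerate(W2):
        acc = np.zeros((len(pos_a), binning.n_bins))
        np.add.at(acc, (ii, kk), w2_row[jj])
        acc *= inv_area
        layer = W1 @ acc  # (n_P1, n_bins)
        denom = tw1[:, None] * tw2[m2]
        with np.errstate(invalid="ignore", divide="ignore"):
            layer = np.where(denom > 0, layer / np.where(denom > 0, denom, 1.0), np.nan)
        out[:, m2, :] = layer
    return out
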