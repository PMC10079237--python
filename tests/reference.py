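"""Naive double-loop reference implementations used as test oracles.

These deliberately mirror the defining sums term by term, independent of
the vectorised implementations in :mod:`wpcf.spatial`.
"""

from __future__ import annotations

import numpy as np

from wpcf.pointcloud import LabelledPointCloud
from wpcf.spatial import RadialBinning, WeightingSpec, annulus_area, weight


def _distance(a, b, domain):
    dx = abs(a[0] - b[0])
    dy = abs(a[1] - b[1])
    if domain.boundary_mode == "periodic":
        dx = min(dx, domain.width - dx)
        dy = min(dy, domain.height - dy)
    return float(np.hypot(dx, dy))


def brute_cross_pcf(
    cloud: LabelledPointCloud, source: str, target: str, binning: RadialBinning
) -> np.ndarray:
    """Term-by-term evaluation of the cross-PCF sum."""
    dom = cloud.domain
    A = dom.area
    n_src = cloud.count(source)
    n_tgt = cloud.count(target)
    values = np.full(binning.n_bins, np.nan)
    if n_src == 0 or n_tgt == 0:
        return values
    for k in range(binning.n_bins):
        r_k = k * binning.dr
        total = 0.0
        for i in range(len(cloud)):
            if cloud.categories[i] != source:
                continue
            area = annulus_area(cloud.positions[i], r_k, binning.dr, dom)
            for j in range(len(cloud)):
                if j == i or cloud.categories[j] != target:
                    continue
                r = _distance(cloud.positions[i], cloud.positions[j], dom)
                if r_k <= r < r_k + binning.dr and area > 0:
                    total += A / area
        values[k] = total / (n_src * n_tgt)
    return values


def brute_wpcf(
    cloud: LabelledPointCloud,
    target: str,
    binning: RadialBinning,
    P_grid: np.ndarray,
    spec: WeightingSpec,
) -> np.ndarray:
    """Term-by-term evaluation of the weighted PCF sum."""
    dom = cloud.domain
    A = dom.area
    n_tgt = cloud.count(target)
    out = np.full((len(P_grid), binning.n_bins), np.nan)
    carriers = [i for i in range(len(cloud)) if not np.isnan(cloud.marks[i])]
    if n_tgt == 0:
        return out
    for m, P in enumerate(P_grid):
        W_P = sum(float(weight(spec, P, cloud.marks[i])) for i in carriers)
        if W_P == 0:
            continue
        for k in range(binning.n_bins):
            r_k = k * binning.dr
            total = 0.0
            for i in carriers:
                w = float(weight(spec, P, cloud.marks[i]))
                if w == 0:
                    continue
                area = annulus_area(cloud.positions[i], r_k, binning.dr, dom)
                for j in range(len(cloud)):
                    if j == i or cloud.categories[j] != target:
                        continue
                    r = _distance(cloud.positions[i], cloud.positions[j], dom)
                    if r_k <= r < r_k + binning.dr and area > 0:
                        total += w * A / area
            out[m, k] = total / (W_P * n_tgt)
    return out


def monte_carlo_annulus_area(
    center, r_k, dr, domain, n_samples, rng
) -> tuple[float, float]:
    """Monte-Carlo estimate of the clipped annulus area, with its own
    standard error.

    Samples points uniformly inside the annulus itself (inverse-CDF in the
    radius), then multiplies the in-rectangle fraction by the full ring
    area -- far lower variance than bounding-box rejection for thin rings.
    The returned standard error lets callers distinguish implementation
    error from the oracle's sampling noise (dominant for sliver overlaps).
    """
    R = r_k + dr
    u = rng.uniform(0.0, 1.0, n_samples)
    r = np.sqrt(r_k**2 + u * (R**2 - r_k**2))
    theta = rng.uniform(0.0, 2 * np.pi, n_samples)
    x = center[0] + r * np.cos(theta)
    y = center[1] + r * np.sin(theta)
    inside = (
        (x >= domain.x_min)
        & (x <= domain.x_max)
        & (y >= domain.y_min)
        & (y <= domain.y_max)
    )
    ring = np.pi * (R**2 - r_k**2)
    p = inside.mean()
    se = ring * np.sqrt(p * (1.0 - p) / n_samples)
    return float(p * ring), float(se)
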