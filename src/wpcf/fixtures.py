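"""Deterministic generators of point patterns with known spatial structure.

These constructions make every statistic testable without running the full
tumour simulation: a line-of-crosses pattern whose marks encode distance to
the line (so the wPCF ridge is known analytically), complete spatial
randomness (the normalising null model), and a generalised banded pattern
with a declared distance-to-mark law plus bounded noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud import Domain, LabelledPointCloud

__all__ = ["LinePatternSpec", "make_line_pattern", "make_csr", "make_banded"]


@dataclass(frozen=True)
class LinePatternSpec:
    """Line-of-crosses construction for validating ridge recovery.

    ``n_crosses`` category-B points are equally spaced on the line y = 1 of a
    square of edge ``edge``; ``n_circles`` category-M points are uniformly
    random with mark |1 - y| (``linear``) or |1 - y|^2 (``quadratic``), so
    each mark equals a known function of the distance to the line and the
    wPCF surface should peak along P = r (resp. P = r^2).
    """

    variant: str = "linear"
    n_crosses: int = 200
    n_circles: int = 1000
    edge: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("linear", "quadratic"):
            raise ValueError("variant must be 'linear' or 'quadratic'")
        if self.n_crosses < 1 or self.n_circles < 1:
            raise ValueError("need at least one cross and one circle")


def make_line_pattern(spec: LinePatternSpec) -> LabelledPointCloud:
    """Build the line-of-crosses validation pattern for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    # midpoint spacing avoids putting crosses on the domain corners
    xs = (np.arange(spec.n_crosses) + 0.5) * (spec.edge / spec.n_crosses)
    crosses = np.column_stack([xs, np.ones(spec.n_crosses)])
    circles = rng.uniform(0.0, spec.edge, size=(spec.n_circles, 2))
    dist = np.abs(1.0 - circles[:, 1])
    marks_c = dist if spec.variant == "linear" else dist**2
    positions = np.vstack([crosses, circles])
    categories = np.array(["B"] * spec.n_crosses + ["M"] * spec.n_circles)
    marks = np.concatenate([np.full(spec.n_crosses, np.nan), marks_c])
    domain = Domain(0.0, spec.edge, 0.0, spec.edge)
    return LabelledPointCloud(positions, categories, marks, domain)


def make_csr(
    n_a: int,
    n_b: int,
    domain: Domain,
    seed: int = 0,
    mark_distribution: str | None = None,
    category_a: str = "B",
    category_b: str = "M",
) -> LabelledPointCloud:
    """Two independent uniform populations (complete spatial randomness).

    Population a gets ``category_a`` (default B) and no marks; population b
    gets ``category_b`` (default M) and, when ``mark_distribution`` is
    ``"uniform"``, i.i.d. uniform marks in [0, 1].  All PCF statistics of
    such a pattern have expectation 1 wherever defined.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    pos_a = np.column_stack(
        [
            rng.uniform(domain.x_min, domain.x_max, n_a),
            rng.uniform(domain.y_min, domain.y_max, n_a),
        ]
    )
    pos_b = np.column_stack(
        [
            rng.uniform(domain.x_min, domain.x_max, n_b),
            rng.uniform(domain.y_min, domain.y_max, n_b),
        ]
    )
    marks_b = (
        rng.uniform(0.0, 1.0, n_b)
        if mark_distribution == "uniform"
        else np.full(n_b, np.nan)
    )
    return LabelledPointCloud(
        positions=np.vstack([pos_a, pos_b]),
        categories=np.array([category_a] * n_a + [category_b] * n_b),
        marks=np.concatenate([np.full(n_a, np.nan), marks_b]),
        domain=domain,
    )


def make_banded(
    band_function,
    n_crosses: int = 200,
    n_circles: int = 1000,
    edge: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
) -> LabelledPointCloud:
    """Crosses on y = 1 with circle marks a declared function of distance.

    ``band_function`` maps distance-to-line to a mark in [0, 1]; bounded
    uniform noise of half-width ``noise`` is added and the result clipped to
    [0, 1].  With the identity function and zero noise this reduces to the
    linear line-of-crosses construction (up to placement randomness).
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    xs = (np.arange(n_crosses) + 0.5) * (edge / n_crosses)
    crosses = np.column_stack([xs, np.ones(n_crosses)])
    circles = rng.uniform(0.0, edge, size=(n_circles, 2))
    dist = np.abs(1.0 - circles[:, 1])
    marks_c = np.asarray([band_function(d) for d in dist], dtype=float)
    if noise > 0:
        marks_c = marks_c + rng.uniform(-noise, noise, n_circles)
    marks_c = np.clip(marks_c, 0.0, 1.0)
    return LabelledPointCloud(
        positions=np.vstack([crosses, circles]),
        categories=np.array(["B"] * n_crosses + ["M"] * n_circles),
        marks=np.concatenate([np.full(n_crosses, np.nan), marks_c]),
        domain=Domain(0.0, edge, 0.0, edge),
    )
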