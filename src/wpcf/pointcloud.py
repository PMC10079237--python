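"""Labelled 2D point patterns on bounded rectangular domains.

A point cloud holds cell-centre (or vessel) coordinates together with a
categorical label per point -- B (blood vessel), M (macrophage), S (stromal
cell), T (tumour cell) or N (necrotic cell) -- and, where meaningful, a
continuous mark in [0, 1] (macrophage phenotype: 0 = anti-tumour M1,
1 = pro-tumour M2).  Coordinates are in units of one cell diameter.

Marks on non-macrophage points are *missing* (NaN), never 0: a mark of 0 is
a meaningful M1 phenotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("B", "M", "S", "T", "N")

__all__ = [
    "CATEGORIES",
    "Domain",
    "LabelledPointCloud",
    "read_point_cloud",
    "write_point_cloud",
    "subset_by_category",
]


@dataclass(frozen=True)
class Domain:
    """Bounded rectangular observation window.

    Parameters
    ----------
    x_min, x_max, y_min, y_max : float
        Bounds in cell diameters.
    boundary_mode : {"clipped", "periodic"}
        ``clipped``: annuli used by the spatial statistics are intersected
        with the rectangle (border correction) and distances are Euclidean.
        ``periodic``: the rectangle is a torus; distances wrap and annuli
        never intersect the boundary.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    boundary_mode: str = "clipped"

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("domain must have positive extent in x and y")
        if self.boundary_mode not in ("clipped", "periodic"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Element-wise test that (n, 2) positions lie inside the rectangle."""
        p = np.asarray(positions, dtype=float).reshape(-1, 2)
        return (
            (p[:, 0] >= self.x_min)
            & (p[:, 0] <= self.x_max)
            & (p[:, 1] >= self.y_min)
            & (p[:, 1] <= self.y_max)
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
            "boundary_mode": self.boundary_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Domain":
        return cls(
            x_min=float(d["x_min"]),
            x_max=float(d["x_max"]),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            boundary_mode=d.get("boundary_mode", "clipped"),
        )


@dataclass
class LabelledPointCloud:
    """Points with categorical labels and optional continuous marks.

    Attributes
    ----------
    positions : (n, 2) float array
        Point coordinates in cell diameters.
    categories : (n,) array of single-character strings
        One of ``B, M, S, T, N`` per point.
    marks : (n,) float array
        Continuous mark in [0, 1] where defined, NaN elsewhere.
    domain : Domain
    time : float or None
        Snapshot time in hours, if the cloud came from a simulation.
    """

    positions: np.ndarray
    categories: np.ndarray
    marks: np.ndarray | None = None
    domain: Domain | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.categories = np.asarray(self.categories, dtype="U1")
        n = len(self.positions)
        if len(self.categories) != n:
            raise ValueError("positions and categories disagree in length")
        if self.marks is None:
            self.marks = np.full(n, np.nan)
        self.marks = np.asarray(self.marks, dtype=float).reshape(-1)
        if len(self.marks) != n:
            raise ValueError("positions and marks disagree in length")
        bad = set(np.unique(self.categories)) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}; expected {CATEGORIES}")
        defined = ~np.isnan(self.marks)
        if defined.any() and (
            (self.marks[defined] < 0).any() or (self.marks[defined] > 1).any()
        ):
            raise ValueError("defined marks must lie in [0, 1]")
        if self.domain is None:
            self.domain = _bounding_domain(self.positions)
        if n and not self.domain.contains(self.positions).all():
            raise ValueError("some positions lie outside the domain")

    def __len__(self) -> int:
        return len(self.positions)

    def count(self, category: str) -> int:
        """N_Q: number of points with the given categorical label."""
        return int(np.sum(self.categories == category))

    def category_mask(self, category: str) -> np.ndarray:
        """Boolean selector implementing the label-match indicator Theta(Q, q_i)."""
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return self.categories == category


def _bounding_domain(positions: np.ndarray) -> Domain:
    if len(positions) == 0:
        return Domain(0.0, 1.0, 0.0, 1.0)
    x_min, y_min = positions.min(axis=0)
    x_max, y_max = positions.max(axis=0)
    # degenerate extents (single point / collinear) get a unit pad
    if x_min == x_max:
        x_max = x_min + 1.0
    if y_min == y_max:
        y_max = y_min + 1.0
    return Domain(float(x_min), float(x_max), float(y_min), float(y_max))


class PointCloudParseError(ValueError):
    """Raised when a point-cloud CSV fails validation, naming the bad row."""


def read_point_cloud(path: str | Path, domain: Domain | None = None) -> LabelledPointCloud:
    """Read a point cloud from CSV (columns ``x, y, category, mark``).

    An optional JSON sidecar ``<path>.meta.json`` supplies the domain bounds,
    boundary mode and snapshot time; an explicit ``domain`` argument takes
    precedence.  Without either, the bounding box of the points is used.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"category": str}, float_precision="round_trip")
    required = {"x", "y", "category"}
    if not required.issubset(df.columns):
        raise PointCloudParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    cats = df["category"].fillna("").str.strip()
    bad = ~cats.isin(CATEGORIES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise PointCloudParseError(
            f"{path}: unknown category {cats[bad].iloc[0]!r} at line {row}"
        )
    marks = (
        pd.to_numeric(df["mark"], errors="coerce").to_numpy(dtype=float)
        if "mark" in df.columns
        else np.full(len(df), np.nan)
    )
    defined = ~np.isnan(marks)
    out_of_range = defined & ((marks < 0) | (marks > 1))
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 2
        raise PointCloudParseError(f"{path}: mark outside [0, 1] at line {row}")

    time = None
    if domain is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "domain" in meta:
                domain = Domain.from_dict(meta["domain"])
            time = meta.get("time")
    return LabelledPointCloud(
        positions=df[["x", "y"]].to_numpy(dtype=float),
        categories=cats.to_numpy(dtype="U1"),
        marks=marks,
        domain=domain,
        time=time,
    )


def write_point_cloud(cloud: LabelledPointCloud, path: str | Path) -> None:
    """Write a point cloud as CSV plus a JSON metadata sidecar.

    Undefined marks are written as empty cells (not 0) so the round trip
    preserves the missing/defined distinction.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "x": cloud.positions[:, 0],
            "y": cloud.positions[:, 1],
            "category": cloud.categories,
            "mark": cloud.marks,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"domain": cloud.domain.to_dict()}
    if cloud.time is not None:
        meta["time"] = cloud.time
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def subset_by_category(cloud: LabelledPointCloud, category: str) -> LabelledPointCloud:
    """Points whose label equals ``category``, on the same domain."""
    keep = cloud.category_mask(category)
    return LabelledPointCloud(
        positions=cloud.positions[keep],
        categories=cloud.categories[keep],
        marks=cloud.marks[keep],
        domain=cloud.domain,
        time=cloud.time,
    )
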