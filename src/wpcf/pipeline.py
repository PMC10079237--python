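"""PCF signatures, their vectorisation, and classification of tumour states.

A *PCF signature* summarises one labelled point cloud by three statistics
computed on shared grids:

* wPCF(r, p, B): weighted PCF between macrophage phenotypes and vessels,
* wPCF(r, p, T): weighted PCF between macrophage phenotypes and tumour cells,
* g_BT(r): cross-PCF between vessels and tumour cells.

Flattened and concatenated (wPCF_B row-major over (P, r), then wPCF_T,
then g_BT) these give a high-dimensional vector -- 38,773 entries with the
default grids (191 radial bins, 101 phenotype values).  Undefined entries
(absent phenotypes, no tumour cells) are imputed with 1, the
no-correlation baseline under complete spatial randomness, and recorded in
an imputation mask.

Snapshots are auto-labelled with the three Es of immunoediting:
Elimination (at most ``elimination_max`` tumour cells), Escape (a tumour
cell within ``escape_radius`` of a vessel), else Equilibrium.  PCA reduces
the signature vectors, and a radial-basis-function SVM over the leading
principal components classifies unseen snapshots; projecting a time series
of signatures traces a trajectory through the reduced space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .pointcloud import LabelledPointCloud
from .spatial import (
    CrossPCFResult,
    RadialBinning,
    WeightingSpec,
    WPCFSurface,
    cross_pcf,
    default_P_grid,
    wpcf,
)

__all__ = [
    "PCFSignature",
    "SignatureVector",
    "CLASS_LABELS",
    "ReducedModel",
    "compute_signature",
    "vectorize",
    "auto_label",
    "fit_reduced_model",
    "project",
    "classify",
    "centroid_signature",
    "trajectory",
]

CLASS_LABELS = ("Equilibrium", "Escape", "Elimination")


@dataclass
class PCFSignature:
    """The triple {wPCF(r,p,B), wPCF(r,p,T), g_BT(r)} for one snapshot."""

    wpcf_B: WPCFSurface
    wpcf_T: WPCFSurface
    g_BT: CrossPCFResult
    time: float | None = None

    @property
    def binning(self) -> RadialBinning:
        return self.wpcf_B.binning

    @property
    def P_grid(self) -> np.ndarray:
        return self.wpcf_B.P_grid


@dataclass
class SignatureVector:
    """Flattened, imputed concatenation of a PCF signature.

    ``imputation_mask`` marks entries that were undefined before being
    replaced by 1 (the CSR baseline).
    """

    values: np.ndarray
    imputation_mask: np.ndarray
    n_bins: int
    n_P: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.imputation_mask = np.asarray(self.imputation_mask, dtype=bool).reshape(-1)
        expected = self.n_bins * (2 * self.n_P + 1)
        if len(self.values) != expected:
            raise ValueError(
                f"vector length {len(self.values)} != n_bins(2 n_P + 1) = {expected}"
            )

    def __len__(self) -> int:
        return len(self.values)


def compute_signature(
    cloud: LabelledPointCloud,
    binning: RadialBinning | None = None,
    P_grid: np.ndarray | None = None,
    spec: WeightingSpec | None = None,
) -> PCFSignature:
    """Compute the three-statistic signature of a snapshot on shared grids.

    Components that cannot be estimated (no tumour cells, missing
    phenotypes) are preserved as undefined, not silently filled.
    """
    binning = binning or RadialBinning()
    P_grid = default_P_grid() if P_grid is None else np.asarray(P_grid, dtype=float)
    spec = spec or WeightingSpec()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-population warnings are expected
        return PCFSignature(
            wpcf_B=wpcf(cloud, "B", binning, P_grid, spec),
            wpcf_T=wpcf(cloud, "T", binning, P_grid, spec),
            g_BT=cross_pcf(cloud, "B", "T", binning),
            time=cloud.time,
        )


def vectorize(signature: PCFSignature) -> SignatureVector:
    """Flatten a signature to [wPCF_B (P,r) row-major, wPCF_T, g_BT].

    Undefined entries become 1 (the CSR no-correlation baseline) and are
    flagged in the imputation mask.  With the default grids the vector has
    191 * (2 * 101 + 1) = 38,773 entries.
    """
    if signature.wpcf_T.binning != signature.binning or signature.g_BT.binning != signature.binning:
        raise ValueError("signature components use different radial binnings")
    if not np.array_equal(signature.wpcf_B.P_grid, signature.wpcf_T.P_grid):
        raise ValueError("signature components use different mark grids")
    parts = [
        signature.wpcf_B.values.reshape(-1),
        signature.wpcf_T.values.reshape(-1),
        signature.g_BT.values.reshape(-1),
    ]
    raw = np.concatenate(parts)
    mask = np.isnan(raw)
    values = np.where(mask, 1.0, raw)
    return SignatureVector(
        values=values,
        imputation_mask=mask,
        n_bins=signature.binning.n_bins,
        n_P=len(signature.P_grid),
    )


def unvectorize(
    values: np.ndarray, n_bins: int, n_P: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the vectorize layout into (wpcf_B, wpcf_T, g_BT) arrays."""
    values = np.asarray(values, dtype=float).reshape(-1)
    block = n_P * n_bins
    if len(values) != 2 * block + n_bins:
        raise ValueError("vector length inconsistent with the given grids")
    return (
        values[:block].reshape(n_P, n_bins),
        values[block : 2 * block].reshape(n_P, n_bins),
        values[2 * block :],
    )


def auto_label(
    cloud: LabelledPointCloud,
    elimination_max: int = 5,
    escape_radius: float = 1.0,
) -> str:
    """Label a snapshot as Elimination, Escape or Equilibrium.

    Elimination: at most ``elimination_max`` tumour cells remain (total or
    near-total clearance).  Otherwise Escape if any tumour cell lies within
    ``escape_radius`` cell diameters of a vessel (it has reached the
    vasculature).  Otherwise Equilibrium (a contained tumour).
    """
    n_tum = cloud.count("T")
    if n_tum <= elimination_max:
        return "Elimination"
    vessels = cloud.positions[cloud.category_mask("B")]
    if len(vessels) == 0:
        return "Equilibrium"
    tumour = cloud.positions[cloud.category_mask("T")]
    d_min = cKDTree(vessels).query(tumour)[0].min()
    return "Escape" if d_min <= escape_radius else "Equilibrium"


@dataclass
class ReducedModel:
    """PCA basis plus an RBF-kernel SVM over the leading components."""

    pca: PCA
    svm: SVC
    n_components: int
    n_bins: int
    n_P: int
    classes_: list = field(default_factory=list)

    @property
    def is_fitted(self) -> bool:
        return hasattr(self.svm, "support_")


def _stack(vectors: list[SignatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(vectors)
    return np.vstack([v.values for v in vectors])


def fit_reduced_model(
    vectors: list[SignatureVector],
    labels: list[str],
    n_components: int = 100,
) -> ReducedModel:
    """Fit PCA on mean-centred signature vectors, then an RBF SVM.

    ``n_components`` is truncated to what the training set can support
    (at most n_samples); the SVM uses scikit-learn's default
    regularisation and kernel-width conventions.
    """
    X = _stack(vectors)
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    k = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=k)
    Z = pca.fit_transform(X)
    svm = SVC(kernel="rbf")
    svm.fit(Z, y)
    model = ReducedModel(
        pca=pca,
        svm=svm,
        n_components=k,
        n_bins=0,
        n_P=0,
        classes_=list(svm.classes_),
    )
    if vectors and isinstance(vectors, list):
        model.n_bins = vectors[0].n_bins
        model.n_P = vectors[0].n_P
    return model


def project(
    model: ReducedModel, vector: SignatureVector | np.ndarray, k: int | None = None
) -> np.ndarray:
    """Coordinates of a signature vector in the fitted PCA basis.

    Returns the first ``k`` coordinates (default: all fitted components).
    """
    k = model.n_components if k is None else k
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds the fitted {model.n_components} components")
    values = vector.values if isinstance(vector, SignatureVector) else np.asarray(vector)
    if values.reshape(-1).shape[0] != model.pca.mean_.shape[0]:
        raise ValueError("vector length does not match the fitted grids")
    return model.pca.transform(values.reshape(1, -1))[0, :k]


def classify(model: ReducedModel, vector: SignatureVector | np.ndarray) -> str:
    """SVM decision over the leading principal components."""
    if not model.is_fitted:
        raise ValueError("model has not been fitted")
    z = project(model, vector)
    return str(model.svm.predict(z.reshape(1, -1))[0])


def centroid_signature(
    model: ReducedModel,
    vectors: list[SignatureVector],
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class centroid truncated to k components, mapped back to signature
    space and reshaped into (wpcf_B, wpcf_T, g_BT) blocks for plotting."""
    if not vectors:
        raise ValueError("need at least one vector")
    k = model.n_components if k is None else k
    Z = np.vstack([project(model, v) for v in vectors])
    centroid = Z.mean(axis=0)
    truncated = np.zeros(model.n_components)
    truncated[:k] = centroid[:k]
    values = model.pca.inverse_transform(truncated.reshape(1, -1))[0]
    n_bins = vectors[0].n_bins
    n_P = vectors[0].n_P
    return unvectorize(values, n_bins, n_P)


def trajectory(
    model: ReducedModel,
    snapshots: list[LabelledPointCloud],
    k: int = 3,
    binning: RadialBinning | None = None,
    P_grid: np.ndarray | None = None,
    spec: WeightingSpec | None = None,
) -> list[tuple[float, np.ndarray]]:
    """Project a time series of snapshots onto the leading components.

    Returns [(time, coordinates), ...] in snapshot order, one entry per
    snapshot, tracing the simulation's path through signature space.
    """
    out = []
    for cloud in snapshots:
        vec = vectorize(compute_signature(cloud, binning, P_grid, spec))
        t = cloud.time if cloud.time is not None else float(len(out))
        out.append((t, project(model, vec, k)))
    return out
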