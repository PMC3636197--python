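"""Principal-component chemical-space mapping and library-overlap metrics.

The chemical-space map is an unscaled PCA on the 8-descriptor panel
(AlogP, MW, HBD, HBA, rotatable bonds, rings, aromatic rings, FPSA):
descriptors are mean-centered but deliberately *not* standardized, so
large-variance descriptors (molecular weight above all) dominate the
leading components — the convention under which the map is interpreted.
Overlap between two libraries is quantified with a percentile bounding
box in score space, which is robust to the extreme outliers natural
product libraries always contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PcaModel:
    """Fitted principal-component model.

    Attributes
    ----------
    component_loadings : (p, k) array
        Unit-norm eigenvectors of the sample covariance matrix, one column
        per retained component, ordered by decreasing explained variance.
    explained_variance_fraction : (k,) array
        Fraction of total variance captured by each retained component.
    training_means : (p,) array
        Column means of the training data (used for centering).
    all_variance_fractions : (p,) array
        Fractions for the full eigen-spectrum; sums to 1.
    """

    component_loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    training_means: np.ndarray
    all_variance_fractions: np.ndarray
    scale: np.ndarray | None = None


@dataclass(frozen=True)
class SpaceOverlap:
    """Mutual containment fractions of two point clouds in score space."""

    fraction_a_in_b: float
    fraction_b_in_a: float


def fit_pca(descriptor_matrix: np.ndarray, k: int = 3, scale: bool = False) -> PcaModel:
    """Fit a covariance-eigendecomposition PCA.

    Parameters
    ----------
    descriptor_matrix : (n, p) array
        Descriptor rows; needs at least ``k + 1`` rows.
    k : int
        Number of components to retain (``k <= p``).
    scale : bool
        If true, divide each column by its sample standard deviation before
        the eigendecomposition (a correlation-matrix PCA). Off by default:
        the chemical-space convention uses raw descriptor units.

    The sign of each component is fixed so that its largest-magnitude
    loading is positive, making fits reproducible across eigensolvers.
    """
    X = np.asarray(descriptor_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptor matrix must be 2-D")
    n, p = X.shape
    if k < 1 or k > p:
        raise ValueError(f"k={k} out of range for {p}-column data")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows to fit {k} components, got {n}")

    means = X.mean(axis=0)
    Xc = X - means
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [int(i) for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"cannot scale constant column(s) {bad}")
        Xc = Xc / sd

    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(p):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.full(p, 1.0 / p)
    return PcaModel(
        component_loadings=eigvecs[:, :k].copy(),
        explained_variance_fraction=fractions[:k].copy(),
        training_means=means,
        all_variance_fractions=fractions,
        scale=sd,
    )


def project(model: PcaModel, descriptor_matrix: np.ndarray) -> np.ndarray:
    """Project descriptor rows into the model's component space.

    Scores are ``(X - training_means) @ loadings`` (divided by the training
    standard deviations first if the model was fitted with scaling).
    """
    X = np.asarray(descriptor_matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    p = model.training_means.shape[0]
    if X.shape[1] != p:
        raise ValueError(f"expected {p} descriptor columns, got {X.shape[1]}")
    Xc = X - model.training_means
    if model.scale is not None:
        Xc = Xc / model.scale
    return Xc @ model.component_loadings


def overlap(scores_a: np.ndarray, scores_b: np.ndarray, percentile: float = 1.0) -> SpaceOverlap:
    """Mutual overlap of two score clouds via percentile bounding boxes.

    ``fraction_a_in_b`` is the fraction of A's points falling inside the
    axis-aligned box spanned by B's 1st–99th percentiles per dimension
    (and symmetrically for ``fraction_b_in_a``). The percentile trim keeps
    a handful of extreme outliers from inflating a library's apparent
    footprint.
    """
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    B = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if len(A) < 10 or len(B) < 10:
        raise ValueError("need at least 10 points per score set")

    def frac_inside(points: np.ndarray, cloud: np.ndarray) -> float:
        lo = np.percentile(cloud, percentile, axis=0)
        hi = np.percentile(cloud, 100.0 - percentile, axis=0)
        inside = np.all((points >= lo) & (points <= hi), axis=1)
        return float(inside.mean())

    return SpaceOverlap(
        fraction_a_in_b=frac_inside(A, B),
        fraction_b_in_a=frac_inside(B, A),
    )
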