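"""Source apportionment: standardization, Ward clustering and varimax PCA.

Clustering operates on the metals (variables), not the samples: the
standardized concentration matrix is transposed so that each metal is an
observation described by its per-sample profile, and Ward/Euclidean
agglomeration is applied.  Euclidean distance between z-scored columns is a
monotone transform of the Pearson correlation (d² = 2(n−1)(1−r)), so metals
that co-vary — shared emission sources or geochemical behaviour — merge early.

PCA is performed on the correlation matrix (z-scored data); components are
retained by the Kaiser criterion (eigenvalue > 1) and the retained loadings
are varimax-rotated.  Rotation redistributes variance among the retained
components but preserves each metal's communality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .samples import SampleTable, ValidationError


def zscore(data: SampleTable | pd.DataFrame) -> pd.DataFrame:
    """Standardize each metal column to mean 0, SD 1 (n−1 denominator)."""
    X = data.matrix() if isinstance(data, SampleTable) else data.copy()
    if len(X) < 2:
        raise ValidationError("zscore requires at least 2 samples")
    sd = X.std(ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValidationError(f"constant column(s): {list(constant)}")
    return (X - X.mean()) / sd


@dataclass
class Dendrogram:
    """A Ward merge sequence over labelled leaves (scipy linkage encoding)."""

    linkage: np.ndarray           # (n-1, 4) scipy linkage matrix
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster membership (1..k) of each leaf at k clusters."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def suggest_k(self) -> int:
        """Cut at the largest increase in fusion height between merges."""
        h = self.heights
        if len(h) < 2:
            return 1
        gaps = np.diff(h)
        # cutting below merge i+1 leaves n_leaves - (i+1) clusters
        i = int(np.argmax(gaps))
        return len(self.labels) - (i + 1)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.labels)
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_h):
            length = parent_h - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(
    data: SampleTable | pd.DataFrame | np.ndarray,
    labels: tuple[str, ...] | None = None,
    on: str = "metals",
) -> Dendrogram:
    """Ward/Euclidean agglomeration.

    For a SampleTable/DataFrame the columns are z-scored and transposed so the
    metals are clustered (``on="samples"`` clusters rows instead).  A plain
    ndarray is used as the observation matrix directly (rows = leaves) and
    requires ``labels``.
    """
    if isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=float)
        if labels is None:
            labels = tuple(f"L{i}" for i in range(X.shape[0]))
    else:
        Z = zscore(data)
        if on == "metals":
            X = Z.to_numpy().T
            labels = tuple(Z.columns)
        elif on == "samples":
            X = Z.to_numpy()
            labels = tuple(str(i) for i in Z.index)
        else:
            raise ValidationError("on must be 'metals' or 'samples'")
    if X.shape[0] < 3:
        raise ValidationError("clustering needs at least 3 leaves")
    link = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(link, tuple(labels))


def _varimax(loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-12):
    """Classic varimax rotation (orthogonal); returns rotated loadings."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L @ np.diag(np.sum(L**2, axis=0))) / p)
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new < d_old * (1 + tol):
            break
        d_old = d_new
    return loadings @ R


@dataclass
class PCAResult:
    """Correlation-matrix PCA with Kaiser retention and optional varimax."""

    loadings: pd.DataFrame          # metals x retained components
    eigenvalues: np.ndarray         # all eigenvalues, descending
    explained: np.ndarray           # variance fractions of retained components
    retained: int
    rotation: str

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


def pca_varimax(
    data: SampleTable | pd.DataFrame,
    rotate: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Eigendecomposition of the correlation matrix, Kaiser retention, varimax.

    ``n_components`` overrides the Kaiser criterion.  Loadings are eigenvectors
    scaled by sqrt(eigenvalue); each column is sign-flipped so its largest-
    magnitude entry is positive (rotation/reflection indeterminacy).
    """
    Z = zscore(data)
    n, p = Z.shape
    if p < 2:
        raise ValidationError("PCA needs at least 2 metals")
    if n <= p:
        import warnings

        warnings.warn(
            f"only {n} samples for {p} variables; loadings are unstable",
            stacklevel=2,
        )
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    if n_components is None:
        k = max(1, int(np.sum(evals > 1.0)))
    else:
        k = int(n_components)
    load = evecs[:, :k] * np.sqrt(evals[:k])
    rotation = "none"
    if rotate and k >= 2:
        load = _varimax(load)
        rotation = "varimax"
    # sign convention
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    explained = (load**2).sum(axis=0) / p
    frame = pd.DataFrame(
        load, index=Z.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAResult(frame, evals, explained, k, rotation)


def interpret_loadings(
    result: PCAResult, strong: float = 0.5, moderate: float = 0.3
) -> pd.DataFrame:
    """Label each |loading| as strong (>0.5), moderate (0.3–0.5) or weak."""
    def lab(v: float) -> str:
        a = abs(v)
        if a > strong:
            return "strong"
        if a >= moderate:
            return "moderate"
        return "weak"

    return result.loadings.map(lab)
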