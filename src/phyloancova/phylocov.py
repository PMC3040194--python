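"""Residual covariance structures for cross-species regression.

Three structures are supported, matching the three estimators:

* ``star`` — identity matrix (a star phylogeny; ordinary least squares);
* ``bm``   — Brownian motion on an ultrametric tree rescaled to height 1:
  entry (i, j) is the depth of the most recent common ancestor of tips i and
  j (their shared root-to-tip path length), so the diagonal is 1;
* ``ou``   — an Ornstein-Uhlenbeck branch-length transform indexed by
  d in [0, 1].  Writing d = e^(-alpha) for the OU restraining strength on
  the height-1 tree, a pair of tips whose MRCA sits at depth s has
  covariance d^(2(1-s)) * (1 - d^(2s)) / (1 - d^2), which is the unit-root
  OU tip covariance normalized to unit diagonal.  d = 1 recovers the
  Brownian matrix, d -> 0 the star phylogeny, connecting the PGLS and OLS
  estimators through a single parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import PhyloTree, TreeStructureError

__all__ = [
    "CovarianceSpec",
    "star_covariance",
    "bm_covariance",
    "ou_covariance",
    "mrca_depth_matrix",
    "ou_transform",
]

#: smallest eigenvalue tolerated before a matrix is declared non-PSD
PSD_TOL = 1e-10


@dataclass
class CovarianceSpec:
    """A residual covariance model and its realized matrix.

    ``species`` states the row/column order; ``d`` is set only for kind='ou'.
    """

    kind: str  # 'star' | 'bm' | 'ou'
    matrix: np.ndarray
    species: tuple[str, ...]
    d: float | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self):
        """Matrix as a labeled DataFrame (species header row/column), TSV-ready."""
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.species), columns=list(self.species))

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.species):
            raise ValueError("species order does not match matrix dimension")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        eigmin = float(np.linalg.eigvalsh(m)[0])
        if eigmin < -PSD_TOL:
            raise ValueError(f"covariance matrix is not PSD (min eigenvalue {eigmin:.3e})")


def _check_unit_ultrametric(tree: PhyloTree, rtol: float = 1e-8) -> None:
    if not tree.is_ultrametric(rtol=rtol):
        raise TreeStructureError(
            "tree is not ultrametric; assign ultrametric branch lengths first"
        )
    if abs(tree.height - 1.0) > rtol:
        raise TreeStructureError(
            f"tree height is {tree.height:.6g}, expected 1; "
            "call rescaled_to_unit_height() first"
        )


def mrca_depth_matrix(tree: PhyloTree) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pairwise MRCA depths (shared root-to-tip path lengths) for all tips.

    Returns the n x n matrix in the tree's tip order plus that order's labels.
    The diagonal holds each tip's own depth.
    """
    tips = tree.tips
    tip_index = {nid: i for i, nid in enumerate(tips)}
    depths = tree.depths()
    n = len(tips)
    S = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_tip:
            below[nid] = np.array([tip_index[nid]])
            continue
        child_sets = [below.pop(c) for c in node.children]
        depth = depths[nid]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                S[np.ix_(child_sets[a], child_sets[b])] = depth
                S[np.ix_(child_sets[b], child_sets[a])] = depth
        below[nid] = np.concatenate(child_sets)
    for nid, i in tip_index.items():
        S[i, i] = depths[nid]
    return S, tuple(tree.nodes[nid].label for nid in tips)


def star_covariance(species: tuple[str, ...]) -> CovarianceSpec:
    """Identity covariance (star phylogeny / ordinary least squares)."""
    spec = CovarianceSpec("star", np.eye(len(species)), tuple(species))
    spec.validate()
    return spec


def bm_covariance(tree: PhyloTree, validate: bool = True) -> CovarianceSpec:
    """Brownian-motion covariance on a height-1 ultrametric tree (unit diagonal)."""
    _check_unit_ultrametric(tree)
    S, species = mrca_depth_matrix(tree)
    np.fill_diagonal(S, 1.0)  # tip depths are 1 up to rounding; enforce exactly
    spec = CovarianceSpec("bm", S, species)
    if validate:
        spec.validate()
    return spec


def ou_transform(S: np.ndarray, d: float) -> np.ndarray:
    """Apply the OU transform elementwise to a matrix of MRCA depths s in [0, 1].

    f(s, d) = d^(2(1-s)) * (1 - d^(2s)) / (1 - d^2); f(1, d) = 1 for all d,
    f(s, 1) = s (Brownian limit, by continuity), f(s, 0+) = 0 for s < 1.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"OU parameter d must lie in [0, 1], got {d}")
    n = S.shape[0]
    if d == 0.0:
        return np.eye(n)
    if d == 1.0:
        return S.copy()
    logd = np.log(d)
    # expm1 keeps the (1 - d^(2s)) / (1 - d^2) ratio stable as d -> 1
    V = np.exp(2.0 * (1.0 - S) * logd) * (np.expm1(2.0 * S * logd) / np.expm1(2.0 * logd))
    np.fill_diagonal(V, 1.0)
    return V


def ou_covariance(tree: PhyloTree, d: float, validate: bool = True) -> CovarianceSpec:
    """OU-transformed covariance on a height-1 ultrametric tree, unit diagonal."""
    bm = bm_covariance(tree, validate=False)
    spec = CovarianceSpec("ou", ou_transform(bm.matrix, float(d)), bm.species, d=float(d))
    if validate:
        spec.validate()
    return spec
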