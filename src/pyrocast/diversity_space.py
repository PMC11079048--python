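"""Six-descriptor chemical-space analysis with PCA.

Flavours and their predicted pyrolysis products are embedded in the
space of six pharmaceutically relevant descriptors (MW, nHBDon, nHBAcc,
TopoPSA, nRotB, ALogP); principal components summarize how tightly the
set clusters and which properties carry the variance.  Columns are
z-standardized by default because the descriptors live on incommensurate
scales (Da, counts, A^2, log units); the flag is exposed since an
unscaled analysis weights everything by molecular weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chem_core import DESCRIPTOR_NAMES, Molecule, descriptor_vector

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "DegenerateInputError",
    "build_descriptor_matrix",
    "pca_project",
]


class DegenerateInputError(ValueError):
    """Matrix has no variance left to decompose."""


@dataclass(frozen=True)
class PCAResult:
    component_loadings: pd.DataFrame   # columns PC1..PCk, rows descriptors
    variance_ratios: np.ndarray        # non-increasing, sums to 1
    coordinates: pd.DataFrame          # leading (up to 3) PC projections


def build_descriptor_matrix(
    mols: list[Molecule], ids: list[str] | None = None
) -> pd.DataFrame:
    """One row per molecule, the six descriptors in fixed column order.

    Rows whose descriptor computation fails are excluded with a log
    message rather than poisoning the matrix.
    """
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules for a descriptor matrix")
    if ids is None:
        ids = [m.canonical_smiles for m in mols]
    rows, kept = [], []
    for mol_id, mol in zip(ids, mols):
        try:
            rows.append(descriptor_vector(mol).as_array())
            kept.append(mol_id)
        except Exception as exc:
            logger.warning("descriptor failure for %s: %s; row excluded", mol_id, exc)
    return pd.DataFrame(rows, index=kept, columns=list(DESCRIPTOR_NAMES))


def pca_project(matrix: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Full PCA of the descriptor matrix; coordinates on the 3 leading PCs.

    With ``standardize`` on, zero-variance columns are dropped with a
    warning (they carry no information and break the z-scale); a matrix
    with no varying column at all is a degenerate input.
    """
    if len(matrix) < 3:
        raise ValueError("PCA requires at least 3 rows")
    X = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    std = X.std(axis=0, ddof=0)
    if standardize:
        varying = std > 0
        if not varying.any():
            raise DegenerateInputError("all descriptor columns are constant")
        dropped = [c for c, v in zip(cols, varying) if not v]
        if dropped:
            logger.warning("dropping zero-variance columns before PCA: %s", dropped)
        X = X[:, varying]
        cols = [c for c, v in zip(cols, varying) if v]
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    else:
        if not (std > 0).any():
            raise DegenerateInputError("all descriptor columns are constant")
        X = X - X.mean(axis=0)

    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    # pin component signs to the loadings (largest-|loading| entry positive)
    # so the projection is invariant to row order
    comps = pca.components_
    for k in range(comps.shape[0]):
        pivot = np.argmax(np.abs(comps[k]))
        if comps[k, pivot] < 0:
            comps[k] *= -1
            scores[:, k] *= -1
    k = min(3, scores.shape[1])
    pc_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        component_loadings=pd.DataFrame(
            pca.components_.T, index=cols, columns=pc_names),
        variance_ratios=ratios,
        coordinates=pd.DataFrame(
            scores[:, :k], index=matrix.index, columns=pc_names[:k]),
    )
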