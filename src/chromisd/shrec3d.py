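"""ShRec3D baseline: shortest-path distance completion + classical MDS.

Contacts and backbone adjacency define a sparse graph; missing entries of
the distance matrix are imputed by all-pairs shortest-path lengths, and a
3D conformation is obtained from the classical (Torgerson) metric MDS
eigendecomposition of the completed matrix.  The overall scale of an MDS
embedding is arbitrary, so benchmark RMSDs are computed after optimal
similarity alignment (rotation + translation + isotropic scale, reflection
allowed) to the ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

from .analysis import superpose
from .likelihoods import ContactData

__all__ = [
    "shortest_path_completion",
    "classical_mds_embed",
    "shrec3d",
    "evaluate_reconstruction",
]


def shortest_path_completion(
    contacts: ContactData,
    n_beads: int,
    contact_dist: float = 1.0,
    backbone_dist: float = 1.0,
) -> np.ndarray:
    """All-pairs shortest-path matrix over contact + backbone edges.

    Loci in experimental contact are placed at ``contact_dist``; neighbors
    along the fiber at ``backbone_dist``.  Backbone edges make the graph
    connected, so the result is a finite metric (zero diagonal, symmetric,
    triangle inequality by construction).
    """
    rows = np.concatenate([contacts.i, np.arange(n_beads - 1)])
    cols = np.concatenate([contacts.j, np.arange(1, n_beads)])
    vals = np.concatenate(
        [np.full(len(contacts), contact_dist), np.full(n_beads - 1, backbone_dist)]
    )
    graph = coo_matrix((vals, (rows, cols)), shape=(n_beads, n_beads))
    D = shortest_path(graph.tocsr(), method="D", directed=False)
    return D


def classical_mds_embed(D: np.ndarray, dim: int = 3) -> tuple[np.ndarray, int]:
    """Classical metric MDS: double-centered Gram matrix, top eigenpairs.

    Coordinates are the leading eigenvectors scaled by the square roots of
    the (nonnegative-clipped) eigenvalues.  Returns (coordinates, rank):
    rank < dim flags a lower-dimensional embedding.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = len(D)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    from scipy.linalg import eigh

    evals, evecs = eigh(B, subset_by_index=[n - dim, n - 1])
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    clipped = np.clip(evals, 0.0, None)
    thresh = max(1e-10, 1e-12 * clipped.max(initial=0.0))
    clipped[clipped <= thresh] = 0.0
    rank = int(np.sum(clipped > 0.0))
    X = evecs * np.sqrt(clipped)[None, :]
    return X, rank


def shrec3d(
    contacts: ContactData,
    n_beads: int,
    contact_dist: float = 1.0,
    backbone_dist: float = 1.0,
) -> np.ndarray:
    """Composed pipeline: shortest-path completion then 3D classical MDS."""
    D = shortest_path_completion(contacts, n_beads, contact_dist, backbone_dist)
    X, _ = classical_mds_embed(D, dim=3)
    return X


def evaluate_reconstruction(X: np.ndarray, ground_truth: np.ndarray) -> float:
    """RMSD to the ground truth after optimal similarity alignment.

    Rotation, translation, isotropic scale and reflection are all allowed
    (the embedding scale and chirality are not identifiable from a graph
    metric).  The result is in the ground truth's length unit — bead radii
    for the lattice benchmarks.
    """
    fit = superpose(
        np.asarray(ground_truth, dtype=float),
        np.asarray(X, dtype=float),
        allow_reflection=True,
        allow_scale=True,
    )
    return float(fit["rmsd"])
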