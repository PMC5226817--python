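"""Post-sampling analytics for conformational ensembles.

Distance-matrix statistics, a band-preserving (diagonal) permutation test
for distance-matrix correlations, least-squares superposition with optional
reflection, spectral clustering of the ensemble on exp(-beta * RMSD)
similarities, per-bead RMSF profiles, restraint-violation counts, contact
probability as a function of genomic separation, and precision/accuracy
against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score

from .likelihoods import ContactData

__all__ = [
    "DistanceMatrixStats",
    "ClusterResult",
    "ensemble_distance_stats",
    "diagonal_permutation_test",
    "superpose",
    "pairwise_rmsd_matrix",
    "cluster_ensemble",
    "rmsf",
    "count_violations",
    "contact_frequency_vs_separation",
    "precision_accuracy",
]


@dataclass
class DistanceMatrixStats:
    """Entry-wise mean and standard deviation of per-member distance matrices."""

    mean: np.ndarray
    sd: np.ndarray


def _as_ensemble(ensemble) -> np.ndarray:
    E = np.asarray(ensemble, dtype=float)
    if E.ndim != 3 or E.shape[2] != 3:
        raise ValueError("ensemble must be an (M, N, 3) array")
    return E


def ensemble_distance_stats(ensemble) -> DistanceMatrixStats:
    """Mean and population sd of the N x N distance matrices of an ensemble."""
    E = _as_ensemble(ensemble)
    if len(E) < 2:
        raise ValueError("need at least two ensemble members")
    dists = np.stack([squareform(pdist(X)) for X in E])
    return DistanceMatrixStats(dists.mean(axis=0), dists.std(axis=0))


def _band_indices(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = []
    for off in range(1, n):
        rows = np.arange(n - off)
        idx.append((rows, rows + off))
    return idx


def diagonal_permutation_test(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Correlation of two distance matrices with a band-preserving null.

    The Pearson correlation is computed over the upper-triangle entries.
    Null matrices are built by independently shuffling the entries of each
    off-diagonal band of ``mean_b``, which preserves the genomic-distance
    structure that makes naive permutation tests anti-conservative.  The
    p-value uses the add-one estimator (1 + #{null >= observed}) / (1 + n).
    """
    A = np.asarray(mean_a, dtype=float)
    B = np.asarray(mean_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a, b = A[iu], B[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for constant matrices")
    observed = float(np.corrcoef(a, b)[0, 1])

    # work in band order: concatenate the off-diagonal bands of both matrices
    bands = _band_indices(n)
    a_bands = np.concatenate([A[r, c] for r, c in bands])
    b_bands = [B[r, c] for r, c in bands]
    a_z = (a_bands - a_bands.mean()) / a_bands.std()
    count = 0
    null_b = np.empty(len(a_bands))
    for _ in range(n_perm):
        pos = 0
        for vals in b_bands:
            m = len(vals)
            null_b[pos : pos + m] = vals[rng.permutation(m)]
            pos += m
        r = float(np.mean(a_z * ((null_b - null_b.mean()) / null_b.std())))
        if r >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, float(p)


def superpose(
    X: np.ndarray,
    Y: np.ndarray,
    allow_reflection: bool = False,
    allow_scale: bool = False,
    mask: np.ndarray | None = None,
) -> dict:
    """Least-squares rigid (optionally similarity) superposition of Y onto X.

    Kabsch/Umeyama solution via SVD.  With ``allow_reflection`` the better
    of the proper and improper alignment is returned and flagged; with
    ``allow_scale`` an optimal isotropic scale is applied to Y.  ``mask``
    selects the beads entering the fit (e.g. to exclude unmappable
    regions).  Returns a dict with rotation, translation, scale, rmsd,
    reflected flag and the transformed copy of Y.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("conformations must have equal bead counts")
    if mask is None:
        Xm, Ym = X, Y
    else:
        mask = np.asarray(mask)
        Xm, Ym = X[mask], Y[mask]
    xc, yc = Xm.mean(axis=0), Ym.mean(axis=0)
    X0, Y0 = Xm - xc, Ym - yc
    C = Y0.T @ X0  # covariance mapping Y -> X
    U, S, Vt = np.linalg.svd(C)

    def build(det_sign: float):
        D = np.eye(3)
        D[2, 2] = det_sign
        R = (U @ D @ Vt).T  # applied as R @ y
        if allow_scale:
            s = (S[0] + S[1] + det_sign * S[2]) / np.sum(Y0**2)
        else:
            s = 1.0
        Yt = s * (Y0 @ R.T)
        rmsd = float(np.sqrt(np.mean(np.sum((Yt - X0) ** 2, axis=1))))
        return R, s, rmsd

    sign_proper = 1.0 if np.linalg.det(U @ Vt) > 0 else -1.0
    R, s, rmsd = build(sign_proper)
    reflected = False
    if allow_reflection:
        R2, s2, rmsd2 = build(-sign_proper)
        if rmsd2 < rmsd:
            R, s, rmsd, reflected = R2, s2, rmsd2, True
    translation = xc - s * (yc @ R.T)
    Y_fit = s * (Y @ R.T) + translation
    return {
        "rotation": R,
        "translation": translation,
        "scale": s,
        "rmsd": rmsd,
        "reflected": reflected,
        "transformed": Y_fit,
    }


def pairwise_rmsd_matrix(
    ensemble, mask: np.ndarray | None = None, allow_reflection: bool = False
) -> np.ndarray:
    """Matrix of pairwise superposition RMSDs between ensemble members.

    Proper rotations only by default, so a structure and its mirror image
    are far apart and separate into distinct clusters.
    """
    E = _as_ensemble(ensemble)
    M = len(E)
    R = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            r = superpose(E[i], E[j], allow_reflection=allow_reflection, mask=mask)["rmsd"]
            R[i, j] = R[j, i] = r
    return R


@dataclass
class ClusterResult:
    """Spectral-clustering summary of a conformational ensemble."""

    labels: np.ndarray
    centers: np.ndarray  # medoid index per cluster
    populations: np.ndarray
    silhouette: float
    K: int
    rmsd_matrix: np.ndarray


def cluster_ensemble(
    ensemble,
    beta: float = 1.0,
    K_range=range(2, 9),
    mask: np.ndarray | None = None,
    rng: int | None = 0,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Spectral clustering on s_ij = exp(-beta RMSD_ij); K by max silhouette.

    ``beta`` defaults to 1/a in internal units.  The cluster center is the
    medoid (member minimizing summed RMSD to co-members).  A degenerate
    ensemble (all members identical) reports K = 1.
    """
    E = _as_ensemble(ensemble)
    M = len(E)
    if M <= max(K_range):
        raise ValueError("ensemble smaller than the largest K requested")
    R = pairwise_rmsd_matrix(E, mask=mask) if rmsd_matrix is None else rmsd_matrix
    if np.allclose(R, 0.0, atol=1e-8):
        return ClusterResult(
            np.zeros(M, dtype=int), np.array([0]), np.array([M]), 1.0, 1, R
        )
    S = np.exp(-beta * R)
    best = None
    for K in K_range:
        sc = SpectralClustering(
            n_clusters=K, affinity="precomputed", random_state=rng, assign_labels="kmeans"
        )
        labels = sc.fit_predict(S)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(R, labels, metric="precomputed")
        if best is None or score > best[0]:
            best = (score, K, labels)
    if best is None:
        return ClusterResult(np.zeros(M, dtype=int), np.array([0]), np.array([M]), 1.0, 1, R)
    score, K, labels = best
    centers = np.array(
        [np.flatnonzero(labels == k)[np.argmin(R[np.ix_(labels == k, labels == k)].sum(axis=1))]
         for k in range(K)]
    )
    populations = np.bincount(labels, minlength=K)
    return ClusterResult(labels, centers, populations, float(score), K, R)


def rmsf(
    members, center: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-bead RMS fluctuation after superposing members onto the center."""
    E = _as_ensemble(members)
    if len(E) < 2:
        raise ValueError("need at least two members")
    center = np.asarray(center, dtype=float)
    sq = np.zeros(E.shape[1])
    for X in E:
        fit = superpose(center, X, mask=mask)["transformed"]
        sq += np.sum((fit - center) ** 2, axis=1)
    return np.sqrt(sq / len(E))


def count_violations(
    ensemble,
    contacts: ContactData,
    d_c: float,
    tolerance: float = 1.0 / 8.0,
    per_member: bool = True,
) -> float:
    """Percentage of contact records violated beyond d_c + tolerance.

    ``per_member`` (default) averages the per-structure violation fraction
    over the ensemble; otherwise the ensemble-mean distances are thresholded.
    """
    E = _as_ensemble(ensemble)
    d = np.linalg.norm(E[:, contacts.i] - E[:, contacts.j], axis=-1)  # (M, C)
    thresh = d_c + tolerance
    if per_member:
        frac = np.mean(d > thresh)
    else:
        frac = np.mean(d.mean(axis=0) > thresh)
    return float(100.0 * frac)


def contact_frequency_vs_separation(ensemble, d_c: float) -> np.ndarray:
    """P(contact) vs genomic separation s (in beads); rows (s, P(s)).

    A (pair, member) event counts as a contact when d_ij < d_c.
    """
    E = _as_ensemble(ensemble)
    N = E.shape[1]
    out = np.zeros((N - 1, 2))
    for s in range(1, N):
        d = np.linalg.norm(E[:, s:] - E[:, :-s], axis=-1)
        out[s - 1] = (s, np.mean(d < d_c))
    return out


def precision_accuracy(
    ensemble,
    ground_truth: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    allow_reflection: bool = False,
) -> tuple[float, float | None]:
    """(precision, accuracy) of an ensemble in the ground truth's units.

    Precision is the average RMSD of the members to the ensemble-average
    structure (members are first superposed onto the first member to remove
    rigid-body scatter).  Accuracy is the RMSD of the average structure to
    the ground truth (None when no truth is supplied).
    """
    E = _as_ensemble(ensemble)
    ref = E[0]
    aligned = np.stack([superpose(ref, X, mask=mask)["transformed"] for X in E])
    mean_X = aligned.mean(axis=0)
    precision = float(
        np.mean([superpose(mean_X, X, mask=mask)["rmsd"] for X in aligned])
    )
    accuracy = None
    if ground_truth is not None:
        accuracy = superpose(
            np.asarray(ground_truth, dtype=float),
            mean_X,
            allow_reflection=allow_reflection,
            mask=mask,
        )["rmsd"]
    return precision, accuracy
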