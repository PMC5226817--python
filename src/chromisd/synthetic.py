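"""Ground-truth generators and data preparation for validation studies.

Provides 3D Hilbert curves as self-avoiding lattice conformations with a
known structure, contact extraction at a distance cutoff, random
sparsification, binning of raw locus pairs onto beads, protein C-alpha
fixtures with distance or contact restraints, and pooled two-structure
contact mixtures for testing ambiguous-restraint (diploid) inference.

Length convention for lattice benchmarks: the lattice spacing equals one
bead radius, so a contact cutoff of 1.5 lattice units captures exactly the
lattice distances {1, sqrt(2)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .likelihoods import ContactData

__all__ = [
    "GroundTruth",
    "hilbert_curve_3d",
    "contacts_from_structure",
    "sparsify_contacts",
    "bin_contacts",
    "ca_fixture",
    "mix_restraints",
    "diploid_mixture_fixture",
]


@dataclass
class GroundTruth:
    """A known conformation with its length convention recorded."""

    conformation: np.ndarray
    lattice_spacing: float = 1.0
    bead_radius: float = 1.0  # in lattice units
    provenance: str = ""

    @property
    def n_beads(self) -> int:
        return len(self.conformation)


def _transpose_to_axes(X: list[int], order: int, ndim: int) -> list[int]:
    # Skilling's transform from the transposed Hilbert index to coordinates
    N = 2 << (order - 1)
    t = X[ndim - 1] >> 1
    for i in range(ndim - 1, 0, -1):
        X[i] ^= X[i - 1]
    X[0] ^= t
    Q = 2
    while Q != N:
        P = Q - 1
        for i in range(ndim - 1, -1, -1):
            if X[i] & Q:
                X[0] ^= P
            else:
                t = (X[0] ^ X[i]) & P
                X[0] ^= t
                X[i] ^= t
        Q <<= 1
    return X


def _index_to_transpose(h: int, order: int, ndim: int) -> list[int]:
    X = [0] * ndim
    for i in range(ndim * order):
        bit = (h >> (ndim * order - 1 - i)) & 1
        X[i % ndim] = (X[i % ndim] << 1) | bit
    return X


def hilbert_curve_3d(order: int) -> GroundTruth:
    """Space-filling self-avoiding path through the 2^order cube lattice.

    Returns 8**order beads visiting every lattice point exactly once, with
    consecutive beads at unit lattice distance.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    n = 8**order
    coords = np.empty((n, 3), dtype=float)
    for h in range(n):
        coords[h] = _transpose_to_axes(_index_to_transpose(h, order, 3), order, 3)
    return GroundTruth(coords, 1.0, 1.0, f"hilbert-3d-order-{order}")


def contacts_from_structure(X: np.ndarray, cutoff: float) -> ContactData:
    """All unordered bead pairs with d_ij <= cutoff, multiplicity 1."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = pdist(X)
    iu = np.triu_indices(n, k=1)
    keep = d <= cutoff
    pairs = np.column_stack([iu[0][keep], iu[1][keep]])
    if len(pairs) == 0:
        return ContactData(np.empty(0, int), np.empty(0, int), np.empty(0), n)
    return ContactData.from_pairs(pairs, n)


def sparsify_contacts(
    contacts: ContactData, n_keep: int, rng: np.random.Generator | int | None = None
) -> ContactData:
    """Uniform subsample of ``n_keep`` contact records without replacement."""
    if not (1 <= n_keep <= len(contacts)):
        raise ValueError("n_keep out of range")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = np.sort(rng.choice(len(contacts), size=n_keep, replace=False))
    return ContactData(
        contacts.i[idx], contacts.j[idx], contacts.counts[idx], contacts.n_beads
    )


def bin_contacts(
    locus_pairs: np.ndarray,
    bin_size_bp: float,
    n_beads: int | None = None,
    return_dropped: bool = False,
):
    """Map raw locus pairs (bp) onto beads; drop self-contacts, merge counts.

    Bead index = floor(pos / bin_size) with half-open bins; pairs landing in
    a single bead (self-contacts) are removed.  Multiple raw pairs mapping
    to one bead pair merge into a single record with incremented n_ij.
    """
    locus_pairs = np.asarray(locus_pairs, dtype=float).reshape(-1, 2)
    if np.any(locus_pairs < 0):
        raise ValueError("negative genomic coordinate")
    if bin_size_bp <= 0:
        raise ValueError("bin size must be positive")
    beads = np.floor(locus_pairs / bin_size_bp).astype(int)
    if n_beads is None:
        n_beads = int(beads.max()) + 1 if len(beads) else 0
    n_self = int(np.sum(beads[:, 0] == beads[:, 1]))
    contacts = ContactData.from_pairs(beads, n_beads)
    if return_dropped:
        return contacts, n_self
    return contacts


def ca_fixture(
    coordinates: np.ndarray,
    distance_cutoff: float | None = None,
    contact_cutoff: float | None = None,
):
    """Restraints from a C-alpha trace, as used for protein-scale tests.

    With ``distance_cutoff`` (e.g. 10 Angstrom) returns the ground truth and
    a record array of (i, j, distance) restraints for all pairs below the
    cutoff; with ``contact_cutoff`` (e.g. 4x the van der Waals radius)
    returns binary contacts instead.  Exactly one cutoff must be given.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate table must be (N, 3)")
    if (distance_cutoff is None) == (contact_cutoff is None):
        raise ValueError("give exactly one of distance_cutoff / contact_cutoff")
    truth = GroundTruth(X, provenance="ca-trace")
    if contact_cutoff is not None:
        return truth, contacts_from_structure(X, contact_cutoff)
    n = len(X)
    d = pdist(X)
    iu = np.triu_indices(n, k=1)
    keep = d < distance_cutoff
    records = np.column_stack([iu[0][keep], iu[1][keep], d[keep]])
    return truth, records


def mix_restraints(records_a: np.ndarray, records_b: np.ndarray, n_beads_a: int, n_beads_b: int):
    """Union of two restraint sets, duplicates kept (ambiguous restraints)."""
    if n_beads_a != n_beads_b:
        raise ValueError("restraint sets to be mixed must share the bead count")
    return np.concatenate([np.asarray(records_a), np.asarray(records_b)], axis=0)


def diploid_mixture_fixture(
    X_a: np.ndarray,
    X_b: np.ndarray,
    cutoff: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[ContactData, np.ndarray]:
    """Pooled, unlabeled contacts of two conformations, plus private labels.

    Returns the union of the per-structure contact sets (multiplicity 1)
    together with a label per pooled record — ``'a'``, ``'b'`` or
    ``'both'`` — retained for evaluating demixing, never for inference.
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape != X_b.shape:
        raise ValueError("conformations must have equal bead counts")
    ca = contacts_from_structure(X_a, cutoff)
    cb = contacts_from_structure(X_b, cutoff)
    n = len(X_a)
    keys_a = set(map(tuple, np.column_stack([ca.i, ca.j])))
    keys_b = set(map(tuple, np.column_stack([cb.i, cb.j])))
    pooled_keys = sorted(keys_a | keys_b)
    pairs = np.asarray(pooled_keys, dtype=int).reshape(-1, 2)
    pooled = ContactData(pairs[:, 0], pairs[:, 1], np.ones(len(pairs)), n)
    labels = np.array(
        [
            "both" if k in keys_a and k in keys_b else ("a" if k in keys_a else "b")
            for k in pooled_keys
        ],
        dtype=object,
    )
    return pooled, labels
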