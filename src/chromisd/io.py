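"""File formats: contact lists, conformations, run configs, sample archives.

Contact lists are tab-separated text, either raw loci with a header
``chrom_i  pos_i  chrom_j  pos_j`` (bp coordinates, one chromosome per
file) or pre-binned ``bead_i  bead_j  count`` records with 0-based bead
indices.  Conformations are written as plain XYZ-style text (index, x, y,
z per line, in units of the bead diameter) and optionally as a PDB-like
pseudo-atom trace for molecular viewers.  Replica-exchange runs are stored
in a single HDF5 archive with per-replica groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .likelihoods import ContactData

__all__ = [
    "FileFormatError",
    "RunConfig",
    "read_contacts",
    "write_contacts",
    "read_xyz",
    "write_xyz",
    "write_pdb_trace",
    "load_config",
    "save_config",
    "save_run_archive",
    "load_run_archive",
]


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_contacts(path, n_beads: int | None = None):
    """Read a contact TSV; returns ContactData or raw locus pairs.

    A ``bead_i``-style header (or 3 numeric columns) yields binned
    :class:`ContactData`; a ``chrom_i``-style header (4 columns) yields an
    (M, 2) float array of bp positions plus the chromosome name, to be
    passed through :func:`chromisd.synthetic.bin_contacts`.
    """
    path = Path(path)
    raw_lines = [
        (lineno, line.strip())
        for lineno, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip() and not line.strip().startswith("#")
    ]
    if not raw_lines:
        raise FileFormatError(f"{path}: no data rows")
    first_fields = raw_lines[0][1].split()
    header = None
    if any(not _is_number(f) for f in first_fields):
        header = [f.lower() for f in first_fields]
        raw_lines = raw_lines[1:]
        if not raw_lines:
            raise FileFormatError(f"{path}: no data rows")

    if header is not None and "chrom_i" in header:
        pi, pj = header.index("pos_i"), header.index("pos_j")
        positions = []
        for lineno, line in raw_lines:
            fields = line.split()
            if len(fields) != len(header):
                raise FileFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns"
                )
            try:
                positions.append([float(fields[pi]), float(fields[pj])])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: not numeric: {line!r}") from exc
        return np.asarray(positions)

    rows = []
    for lineno, line in raw_lines:
        fields = line.split()
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: not numeric: {line!r}") from exc
        if len(rows[-1]) not in (2, 3, 4):
            raise FileFormatError(
                f"{path}:{lineno}: expected 2-4 columns, got {len(rows[-1])}"
            )
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FileFormatError(f"{path}: inconsistent column counts")
    data = np.asarray(rows)
    if width == 4:  # headerless raw loci: pos_i, pos_i, pos_j, pos_j unsupported
        return data[:, [1, 3]]
    pairs = data[:, :2].astype(int)
    counts = data[:, 2] if width == 3 else None
    if n_beads is None:
        n_beads = int(pairs.max()) + 1
    return ContactData.from_pairs(pairs, n_beads, counts)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_contacts(path, contacts: ContactData) -> None:
    with open(path, "w") as fh:
        fh.write("bead_i\tbead_j\tcount\n")
        for i, j, n in zip(contacts.i, contacts.j, contacts.counts):
            fh.write(f"{i}\t{j}\t{n:g}\n")


def write_xyz(path, X: np.ndarray) -> None:
    """One bead per line: index, x, y, z (units of the bead diameter)."""
    X = np.asarray(X, dtype=float)
    with open(path, "w") as fh:
        fh.write("# bead\tx\ty\tz\n")
        for k, (x, y, z) in enumerate(X):
            fh.write(f"{k}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")


def read_xyz(path) -> np.ndarray:
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FileFormatError(f"{path}:{lineno}: expected 4 columns")
        try:
            rows.append([float(f) for f in fields[1:]])
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: not numeric: {raw!r}") from exc
    return np.asarray(rows)


def write_pdb_trace(path, X: np.ndarray, scale_angstrom: float = 10.0) -> None:
    """PDB-like pseudo-atom trace (CA atoms, sequential chain) for viewers."""
    X = np.asarray(X, dtype=float) * scale_angstrom
    with open(path, "w") as fh:
        for k, (x, y, z) in enumerate(X, start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  BEA A{k % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


@dataclass
class RunConfig:
    """Plain-text (key = value) record of everything a run depends on."""

    n_beads: int = 333
    resolution_bp: float = 500_000.0
    bead_diameter_um: float = 0.43
    ev_kind: str = "quartic_repulsion"
    likelihood: str = "logistic"
    diploid: bool = False
    use_fish: bool = False
    fish_s_bar: float = 3.7
    fish_delta_s: float = 0.3
    fish_M: int = 1
    gamma: float = 1.0
    weight: float = 100.0
    sample_gamma: bool = False
    sample_weight: bool = False
    lambda_min: float = 1e-4
    lambda_max: float = 1.0
    n_replicas: int = 50
    n_transitions: int = 1000
    hmc_steps_per_transition: int = 10
    n_leapfrog: int = 250
    burnin_fraction: float = 0.1
    seed: int = 0

    def to_text(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(config.to_text())


def load_config(path) -> RunConfig:
    path = Path(path)
    cfg = RunConfig()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FileFormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(cfg, key):
            raise FileFormatError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        elif isinstance(current, float):
            setattr(cfg, key, float(value))
        else:
            setattr(cfg, key, value)
    return cfg


def save_run_archive(path, run, config: RunConfig | None = None) -> None:
    """Write a replica-exchange run to one HDF5 file (per-replica groups)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("lambdas", data=run.lambdas)
        fh.create_dataset("log_like", data=run.log_like)
        fh.create_dataset("log_prior", data=run.log_prior)
        fh.create_dataset("swap_acceptance", data=run.swap_acceptance)
        fh.create_dataset("hmc_acceptance", data=run.hmc_acceptance)
        fh.create_dataset("timesteps", data=run.timesteps)
        fh.attrs["n_burnin"] = run.n_burnin
        post = fh.create_group("posterior")
        post.create_dataset("positions", data=run.positions)
        if run.positions2 is not None:
            post.create_dataset("positions2", data=run.positions2)
        theta = fh.create_group("theta")
        theta.create_dataset("gamma", data=run.gammas)
        theta.create_dataset("sigma", data=run.sigmas)
        if run.all_positions is not None:
            grp = fh.create_group("replicas")
            for k, pos in enumerate(run.all_positions):
                grp.create_dataset(f"{k:03d}/positions", data=pos)
        if config is not None:
            fh.attrs["config"] = config.to_text()


def load_run_archive(path):
    """Read back the arrays written by :func:`save_run_archive` as a dict."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for key in ("lambdas", "log_like", "log_prior", "swap_acceptance",
                    "hmc_acceptance", "timesteps"):
            out[key] = fh[key][...]
        out["n_burnin"] = int(fh.attrs["n_burnin"])
        out["positions"] = fh["posterior/positions"][...]
        if "positions2" in fh["posterior"]:
            out["positions2"] = fh["posterior/positions2"][...]
        out["gamma"] = fh["theta/gamma"][...]
        out["sigma"] = fh["theta/sigma"][...]
        if "config" in fh.attrs:
            out["config"] = str(fh.attrs["config"])
    return out
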