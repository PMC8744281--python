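"""Read, validate and write FA-weighted structural connectivity matrices.

Each subject's white-matter network is a symmetric matrix whose entry (i, j)
is the fractional anisotropy (FA, in [0, 1]) of the tract connecting regions
i and j; absent connections are exact zeros and the diagonal is zero.
Supported on-disk formats: dense CSV and MatrixMarket symmetric coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .atlas import Parcellation

#: Asymmetries at or below this absolute tolerance are treated as float
#: round-off and symmetrized by averaging; anything larger is corrupt input.
ASYMMETRY_TOL = 1e-9


class ConnectomeError(ValueError):
    """Raised for malformed connectivity matrices."""


@dataclass(frozen=True)
class Connectome:
    subject_id: str
    weights: np.ndarray  # (n, n) symmetric, values in [0, 1], zero diagonal

    def __post_init__(self) -> None:
        validate_weights(self.weights)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_weights(w: np.ndarray, n_expected: int | None = None) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"matrix must be square, got shape {w.shape}")
    if n_expected is not None and w.shape[0] != n_expected:
        raise ConnectomeError(
            f"expected {n_expected}x{n_expected} matrix, got {w.shape[0]}x{w.shape[1]}"
        )
    if np.isnan(w).any():
        i, j = map(int, np.argwhere(np.isnan(w))[0])
        raise ConnectomeError(f"NaN weight at ({i}, {j})")
    if (w < 0).any():
        i, j = map(int, np.argwhere(w < 0)[0])
        raise ConnectomeError(f"negative weight {w[i, j]:g} at ({i}, {j})")
    if (w > 1).any():
        i, j = map(int, np.argwhere(w > 1)[0])
        raise ConnectomeError(f"FA weight {w[i, j]:g} > 1 at ({i}, {j})")
    if np.diag(w).any():
        i = int(np.argwhere(np.diag(w))[0][0])
        raise ConnectomeError(f"nonzero diagonal entry at ({i}, {i})")
    if not np.array_equal(w, w.T):
        raise ConnectomeError("matrix is not symmetric")


def _symmetrize(w: np.ndarray) -> np.ndarray:
    asym = np.abs(w - w.T).max()
    if asym > ASYMMETRY_TOL:
        i, j = map(int, np.argwhere(np.abs(w - w.T) > ASYMMETRY_TOL)[0])
        raise ConnectomeError(
            f"asymmetry {asym:g} at ({i}, {j}) exceeds tolerance {ASYMMETRY_TOL:g}"
        )
    return (w + w.T) / 2.0


def load_connectome(
    path: str | Path,
    parcellation: Parcellation | None = None,
    subject_id: str | None = None,
) -> Connectome:
    """Load a connectome from a dense CSV or MatrixMarket (.mtx) file.

    An optional header row of labels is tolerated in CSV input.  Asymmetries
    within :data:`ASYMMETRY_TOL` are averaged away; larger ones are errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        m = scipy.io.mmread(path)
        w = m.toarray() if scipy.sparse.issparse(m) else np.asarray(m)
    else:
        first = path.open().readline()
        skip = 0 if _looks_numeric(first) else 1
        w = np.loadtxt(path, delimiter=",", skiprows=skip, dtype=float)
    w = np.atleast_2d(np.asarray(w, dtype=float))
    w = _symmetrize(w)
    n_expected = parcellation.n_nodes if parcellation is not None else None
    validate_weights(w, n_expected)
    return Connectome(subject_id or path.stem, w)


def _looks_numeric(line: str) -> bool:
    try:
        float(line.split(",")[0])
        return True
    except ValueError:
        return False


def build_connectome_from_edges(
    edges, parcellation: Parcellation, subject_id: str = "edges"
) -> Connectome:
    """Assemble a connectome from (label_a, label_b, fa) rows.

    Unlisted pairs get weight 0.  Duplicate pairs (in either orientation) and
    self-edges are rejected.
    """
    n = parcellation.n_nodes
    w = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for a, b, fa in edges:
        i, j = parcellation.index_of(a), parcellation.index_of(b)
        if i == j:
            raise ConnectomeError(f"self-edge on {a!r}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ConnectomeError(f"duplicate edge ({a!r}, {b!r})")
        seen.add(key)
        if not 0 <= fa <= 1:
            raise ConnectomeError(f"FA {fa:g} out of [0, 1] for edge ({a!r}, {b!r})")
        w[i, j] = w[j, i] = fa
    return Connectome(subject_id, w)


def write_connectome(connectome: Connectome, path: str | Path) -> Path:
    """Write to CSV or MatrixMarket, chosen by file extension.

    ``load_connectome(write_connectome(x))`` reproduces the matrix at stored
    precision (full repr precision in both formats).
    """
    path = Path(path)
    w = connectome.weights
    if path.suffix.lower() == ".mtx":
        scipy.io.mmwrite(
            path, scipy.sparse.coo_matrix(w), symmetry="symmetric", precision=17
        )
    else:
        np.savetxt(path, w, delimiter=",", fmt="%.17g")
    return path
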