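"""Two-shell diffusion acquisition schemes and FSL-style bval/bvec I/O.

The default scheme mirrors a clinical tumor protocol: 15 b=0 volumes and
58 diffusion-encoding directions repeated on shells at b = 1000 and
2000 s/mm^2.  Directions are laid out with a spherical-Fibonacci lattice,
which is near-uniform on the sphere; since diffusion signals are antipodally
symmetric, full-sphere uniformity is what matters for even-order spherical
harmonic fits and powder averages.

Unit convention: b-values are stored in s/mm^2 at the interface (FSL files)
and converted to ms/um^2 (divide by 1000) for all internal computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import IdentifiabilityError

__all__ = ["AcquisitionScheme", "make_scheme", "fibonacci_directions",
           "save_bval_bvec", "load_bval_bvec", "scheme_from_tables"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_directions(n: int) -> np.ndarray:
    """Return ``n`` unit vectors on a spherical-Fibonacci lattice, shape (n, 3)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionScheme:
    """A multi-shell acquisition: b=0 volumes followed by one direction block per shell.

    Attributes
    ----------
    b_values : tuple of float
        Shell b-values in s/mm^2, including exactly one 0 entry.
    n_b0 : int
        Number of non-diffusion-weighted volumes.
    directions : ndarray, shape (directions_per_shell, 3)
        Unit gradient directions, reused identically on every nonzero shell.
    """

    b_values: tuple[float, ...]
    n_b0: int
    directions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.count_nonzero(b == 0) != 1:
            raise ValueError("scheme must contain exactly one b=0 shell entry")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("gradient directions must be unit vectors")

    @property
    def directions_per_shell(self) -> int:
        return self.directions.shape[0]

    @property
    def nonzero_shells(self) -> tuple[float, ...]:
        """Nonzero shell b-values in s/mm^2, ascending."""
        return tuple(sorted(b for b in self.b_values if b > 0))

    @property
    def shells_ms_um2(self) -> np.ndarray:
        """Nonzero shell b-values in ms/um^2 (internal unit)."""
        return np.asarray(self.nonzero_shells) / 1000.0

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.directions_per_shell * len(self.nonzero_shells)

    def bvals(self) -> np.ndarray:
        """Per-volume b-values in s/mm^2."""
        parts = [np.zeros(self.n_b0)]
        for b in self.nonzero_shells:
            parts.append(np.full(self.directions_per_shell, b))
        return np.concatenate(parts)

    def bvecs(self) -> np.ndarray:
        """Per-volume unit gradient vectors, zero rows for b=0; shape (n_volumes, 3)."""
        parts = [np.zeros((self.n_b0, 3))]
        for _ in self.nonzero_shells:
            parts.append(self.directions)
        return np.vstack(parts)

    def shell_slices(self) -> dict[float, slice]:
        """Volume index slice for each nonzero shell (s/mm^2 keys)."""
        out = {}
        start = self.n_b0
        for b in self.nonzero_shells:
            out[b] = slice(start, start + self.directions_per_shell)
            start += self.directions_per_shell
        return out

    @property
    def b0_slice(self) -> slice:
        return slice(0, self.n_b0)


def make_scheme(n_b0: int = 15, dirs_per_shell: int = 58,
                b_values: tuple[float, ...] = (0.0, 1000.0, 2000.0)) -> AcquisitionScheme:
    """Build a scheme with ``n_b0`` b=0 volumes and a shared Fibonacci direction set.

    Raises
    ------
    IdentifiabilityError
        If fewer than 6 directions are requested (a diffusion tensor has 6
        independent elements).
    """
    if dirs_per_shell < 6:
        raise IdentifiabilityError(
            f"at least 6 directions required for tensor identifiability, got {dirs_per_shell}")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    return AcquisitionScheme(
        b_values=tuple(float(b) for b in b_values),
        n_b0=int(n_b0),
        directions=fibonacci_directions(int(dirs_per_shell)),
    )


def save_bval_bvec(scheme: AcquisitionScheme, bval_path: str | Path,
                   bvec_path: str | Path) -> None:
    """Write FSL-format files: bvals one row; bvecs three rows (x, y, z)."""
    bvals = scheme.bvals()
    bvecs = scheme.bvecs().T  # 3 x n_volumes
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in row) for row in bvecs]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def load_bval_bvec(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-format files; returns (bvals (n,), bvecs (n, 3))."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values")
    return bvals, bvecs


def scheme_from_tables(bvals: np.ndarray, bvecs: np.ndarray,
                       b0_threshold: float = 50.0) -> AcquisitionScheme:
    """Reconstruct an AcquisitionScheme from per-volume tables.

    Assumes the package's own volume layout (b=0 block first, then one
    contiguous block per shell with a shared direction set).
    """
    bvals = np.asarray(bvals, float)
    is_b0 = bvals <= b0_threshold
    shells = sorted(set(np.round(bvals[~is_b0]).tolist()))
    n_b0 = int(is_b0.sum())
    if not shells:
        raise ValueError("no diffusion-weighted volumes found")
    first = np.round(bvals) == shells[0]
    dirs = np.asarray(bvecs, float)[first]
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return AcquisitionScheme(b_values=(0.0, *[float(s) for s in shells]),
                             n_b0=n_b0, directions=dirs)
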