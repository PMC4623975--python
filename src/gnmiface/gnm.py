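"""Gaussian network model core: Kirchhoff matrix, modes, correlation maps.

The elastic network places a node at each C-alpha and connects every residue
pair within a cutoff radius ``r_c`` (default 7 A) by an identical harmonic
spring of constant ``gamma``.  The network potential is

    V = (gamma / 2) * sum_ij Gamma_ij (dR_i - dR_j)^2

with the Kirchhoff (connectivity) matrix

    Gamma_ij = -1        if i != j and R_ij <= r_c
             =  0        if i != j and R_ij >  r_c
    Gamma_ii = -sum_{j != i} Gamma_ij ,

i.e. the graph Laplacian of the contact network; the diagonal is the node
degree, a measure of local packing density.  Equilibrium fluctuations follow
from the eigendecomposition ``Gamma = U Lambda U^T``:

    <dR_i . dR_j> = (3 k_B T / gamma) * sum_k  lambda_k^-1 (u_k u_k^T)_ij

where the sum runs over the selected nonzero modes.  Slow modes (small
``lambda``) carry the global cooperative motions; fast modes describe local
fluctuations.  The trivial zero mode (uniform translation of the whole
network) carries no internal motion and is always excluded; ``lambda^-1``
would diverge on it anyway.

The cutoff comparison is inclusive (``<= r_c``), the common convention;
synthetic fixtures keep pair distances away from exactly 7 A so nothing
downstream depends on the boundary case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.spatial

from .errors import (
    DegenerateFluctuationError,
    ModeSetError,
    SingularNetworkError,
)
from .structure import CalphaTrace, SubunitPartition

__all__ = [
    "GNMParams",
    "KirchhoffMatrix",
    "ModeSpectrum",
    "ModeSet",
    "CorrelationMap",
    "build_kirchhoff",
    "decompose",
    "covariance",
    "normalize",
    "correlation_map",
    "write_map_tsv",
]


@dataclass(frozen=True)
class GNMParams:
    """Model parameters.

    ``cutoff_rc`` is the contact cutoff in Angstrom (7.0 by default).
    ``gamma`` (spring constant) and ``kbt`` (thermal energy) only scale the
    raw covariance; normalized correlations are invariant to both, so the
    defaults of 1 are arbitrary units.  ``zero_eig_tol`` is the *relative*
    tolerance (w.r.t. the largest eigenvalue) below which an eigenvalue
    counts as zero; ``None`` selects the scale-aware default
    ``N * machine_epsilon``.
    """

    cutoff_rc: float = 7.0
    gamma: float = 1.0
    kbt: float = 1.0
    zero_eig_tol: float | None = None

    def __post_init__(self) -> None:
        if self.cutoff_rc <= 0 or self.gamma <= 0 or self.kbt <= 0:
            raise ValueError("cutoff_rc, gamma and kbt must be positive")
        if self.zero_eig_tol is not None and not 0 < self.zero_eig_tol <= 1e-3:
            raise ValueError("zero_eig_tol must lie in (0, 1e-3]")


@dataclass(frozen=True)
class KirchhoffMatrix:
    """Graph Laplacian of the C-alpha contact network, in trace node order."""

    matrix: np.ndarray  # (N, N) symmetric, integer-valued, rows sum to 0
    cutoff_rc: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Kirchhoff matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def degrees(self) -> np.ndarray:
        """Contact degree of each node (the diagonal; local packing density)."""
        return np.diag(self.matrix).copy()


@dataclass(frozen=True)
class ModeSpectrum:
    """Eigenvalues (ascending) and orthonormal eigenvectors of Gamma."""

    eigenvalues: np.ndarray  # (N,)
    eigenvectors: np.ndarray  # (N, N); column k pairs with eigenvalues[k]
    n_zero: int

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nonzero(self) -> int:
        return self.n - self.n_zero

    def nonzero_indices(self) -> np.ndarray:
        return np.arange(self.n_zero, self.n)

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector of internal mode ``k`` (1-based; 1 = slowest nonzero)."""
        if not 1 <= k <= self.n_nonzero:
            raise ModeSetError(
                f"mode {k} out of range; spectrum has {self.n_nonzero} nonzero modes"
            )
        return self.eigenvectors[:, self.n_zero + k - 1]


@dataclass(frozen=True)
class ModeSet:
    """A selection of internal (nonzero) modes.

    ``selector`` is one of ``"slowest_2"``, ``"slowest_10"`` or ``"all"``;
    ``slowest_k`` resolves to the ``min(k, N - n_zero)`` nonzero modes of
    smallest eigenvalue.  Zero modes are never included.
    """

    selector: str
    indices: tuple[int, ...]  # positions in the spectrum's eigenvalue order

    SELECTORS = ("slowest_2", "slowest_10", "all")

    @classmethod
    def resolve(cls, selector: str, spectrum: ModeSpectrum) -> "ModeSet":
        if selector == "all":
            k = spectrum.n_nonzero
        elif selector.startswith("slowest_"):
            k = min(int(selector.split("_")[1]), spectrum.n_nonzero)
        else:
            raise ModeSetError(f"unknown mode-set selector {selector!r}")
        idx = tuple(range(spectrum.n_zero, spectrum.n_zero + k))
        if not idx:
            raise ModeSetError(f"mode set {selector!r} resolved to no modes")
        return cls(selector=selector, indices=idx)


@dataclass(frozen=True)
class CorrelationMap:
    """Raw covariance and normalized cross-correlations for one mode set.

    ``raw[i, j] = <dR_i . dR_j>`` restricted to the mode set;
    ``normalized[i, j] = raw[i, j] / sqrt(raw[i, i] * raw[j, j])`` lies in
    [-1, +1] with an exact unit diagonal.  ``normalized`` is ``None`` until
    :func:`normalize` fills it.
    """

    raw: np.ndarray
    mode_set: ModeSet
    normalized: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.raw.shape[0]


# ---------------------------------------------------------------------------


def build_kirchhoff(trace: CalphaTrace, params: GNMParams = GNMParams()) -> KirchhoffMatrix:
    """Contact-network Laplacian of a trace: -1 off-diagonal within ``r_c``."""
    if len(trace) < 2:
        raise ValueError("need at least 2 residues to build a network")
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(trace.coords))
    contact = d <= params.cutoff_rc
    np.fill_diagonal(contact, False)
    gamma_m = -contact.astype(float)
    np.fill_diagonal(gamma_m, contact.sum(axis=1))
    return KirchhoffMatrix(matrix=gamma_m, cutoff_rc=params.cutoff_rc)


def decompose(
    kirchhoff: KirchhoffMatrix,
    params: GNMParams = GNMParams(),
    on_disconnected: str = "raise",
) -> ModeSpectrum:
    """Eigendecompose Gamma; detect zero modes; reject disconnected networks.

    A connected contact network has exactly one zero eigenvalue.  Two or
    more zero modes mean the network is disconnected -- for a two-subunit
    complex this happens precisely when the minimum inter-subunit C-alpha
    distance exceeds the cutoff -- and the covariance of the complex as a
    whole is undefined, so a :class:`SingularNetworkError` is raised unless
    ``on_disconnected="allow"`` (useful for diagnostics).
    """
    evals, evecs = scipy.linalg.eigh(kirchhoff.matrix)
    lam_max = float(evals[-1]) if len(evals) else 0.0
    rel_tol = params.zero_eig_tol
    if rel_tol is None:
        # scale-aware rank tolerance; the factor 100 covers the spread of
        # symmetric-eigensolver roundoff while staying orders of magnitude
        # below any genuine slow-mode eigenvalue
        rel_tol = 100.0 * kirchhoff.n * np.finfo(float).eps
    n_zero = int(np.sum(evals < rel_tol * max(lam_max, 1.0)))
    spectrum = ModeSpectrum(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero)
    if n_zero >= 2 and on_disconnected == "raise":
        raise SingularNetworkError(
            f"singular connectivity matrix: contact network has {n_zero} "
            "connected components. For a two-subunit complex this means the "
            f"minimum inter-subunit C-alpha distance exceeds the cutoff "
            f"({kirchhoff.cutoff_rc:g} A)."
        )
    return spectrum


def covariance(
    spectrum: ModeSpectrum,
    mode_set: ModeSet | str,
    params: GNMParams = GNMParams(),
) -> CorrelationMap:
    """Raw fluctuation covariance restricted to a mode set.

    ``raw = (3 k_B T / gamma) * sum_{k in set} lambda_k^-1 u_k u_k^T``.
    With ``mode_set="all"`` this equals ``(3 k_B T / gamma)`` times the
    Moore-Penrose pseudoinverse of Gamma.
    """
    if isinstance(mode_set, str):
        mode_set = ModeSet.resolve(mode_set, spectrum)
    if not mode_set.indices:
        raise ModeSetError("empty mode set")
    idx = np.asarray(mode_set.indices)
    if np.any(idx < spectrum.n_zero):
        raise ModeSetError("mode set includes a zero mode")
    u = spectrum.eigenvectors[:, idx]
    inv_lam = 1.0 / spectrum.eigenvalues[idx]
    raw = (3.0 * params.kbt / params.gamma) * (u * inv_lam) @ u.T
    raw = 0.5 * (raw + raw.T)  # enforce exact symmetry
    return CorrelationMap(raw=raw, mode_set=mode_set)


def normalize(cmap: CorrelationMap) -> CorrelationMap:
    """Fill the normalized cross-correlation matrix of a raw map.

    ``C_ij = raw_ij / sqrt(raw_ii raw_jj)``; the diagonal is set to exactly
    1.  Raises :class:`DegenerateFluctuationError` if some residue has no
    fluctuation under the chosen mode set (``raw_ii`` numerically zero), in
    which case the correlation is undefined.
    """
    diag = np.diag(cmap.raw)
    tol = 1e-12 * max(float(diag.max(initial=0.0)), np.finfo(float).tiny)
    if np.any(diag <= tol):
        bad = int(np.argmin(diag))
        raise DegenerateFluctuationError(
            f"residue index {bad} has (numerically) zero mean-square "
            "fluctuation under this mode set"
        )
    scale = 1.0 / np.sqrt(diag)
    c = cmap.raw * np.outer(scale, scale)
    np.fill_diagonal(c, 1.0)
    c = 0.5 * (c + c.T)
    return CorrelationMap(raw=cmap.raw, mode_set=cmap.mode_set, normalized=c)


def correlation_map(
    spectrum: ModeSpectrum,
    selector: str,
    params: GNMParams = GNMParams(),
) -> CorrelationMap:
    """Convenience: resolved, covariance-filled, normalized map in one call."""
    return normalize(covariance(spectrum, selector, params))


def write_map_tsv(
    cmap: CorrelationMap,
    trace: CalphaTrace,
    which: str = "normalized",
) -> str:
    """Serialize a correlation map as tab-delimited text.

    Rows and columns are labeled with ``chain:RESNAMEnumber`` residue keys;
    the first header cell names the mode set and variant.
    """
    if which == "normalized":
        if cmap.normalized is None:
            raise ValueError("map has no normalized part; call normalize() first")
        m = cmap.normalized
    elif which == "raw":
        m = cmap.raw
    else:
        raise ValueError("which must be 'normalized' or 'raw'")
    if m.shape[0] != len(trace):
        raise ValueError("map and trace sizes disagree")
    labels = [trace.label(i) for i in range(len(trace))]
    lines = ["\t".join([f"{which}:{cmap.mode_set.selector}"] + labels)]
    for lab, row in zip(labels, m):
        lines.append("\t".join([lab] + [f"{v:.6f}" for v in row]))
    return "\n".join(lines) + "\n"


def min_intersubunit_distance(
    trace: CalphaTrace, partition: SubunitPartition
) -> float:
    """Minimum C-alpha distance between the two subunits (diagnostic)."""
    i1, i2 = partition.indices(trace)
    d = scipy.spatial.distance.cdist(trace.coords[i1], trace.coords[i2])
    return float(d.min())
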