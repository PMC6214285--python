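"""Graph Laplacians and the random-walk normalized Fiedler pair.

The bridge-finding half of the Protection Value rests on the second-smallest
eigenpair (algebraic connectivity alpha, Fiedler vector mu) of the random-walk
normalized Laplacian L_rw = I - D^{-1}A.  L_rw is similar to the symmetric
normalized Laplacian L_sym = I - D^{-1/2} A D^{-1/2} via
L_rw = D^{-1/2} L_sym D^{1/2}, so the eigenpair is computed on the symmetric
form and back-transformed — numerically safer than iterating on the
non-symmetric L_rw.

Conventions for degenerate inputs: directed adjacencies are symmetrized
(A + A^T, binarized) before any Laplacian; rows and columns of zero-degree
nodes are zero in both normalized Laplacians, so isolated copies get a zero
Fiedler entry and never rank as bridges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralResult",
    "combinatorial_laplacian",
    "rw_normalized_laplacian",
    "sym_normalized_laplacian",
    "fiedler_rw",
    "zero_multiplicity",
]

#: below this many nodes the dense eigensolver is used outright
DENSE_THRESHOLD = 500
#: default eigensolver tolerance
DEFAULT_TOL = 1e-8
#: iteration cap for the sparse eigensolver (per ARPACK restart convention)
MAX_ITER_FACTOR = 50


@dataclass
class SpectralResult:
    """Second-smallest eigenpair of L_rw.

    alpha lies in [0, 2]; mu has unit Euclidean norm and its sign is
    canonicalized (first entry of magnitude > 1e-12 is positive), which makes
    repeated computations bitwise identical.  zero_multiplicity equals the
    number of connected components of the underlying graph.
    """

    alpha: float
    mu: np.ndarray
    tolerance: float
    zero_multiplicity: int


def _as_sparse(A) -> sp.csr_array:
    if sp.issparse(A):
        return sp.csr_array(A)
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    return sp.csr_array(A)


def _symmetrize(A: sp.csr_array) -> sp.csr_array:
    """Return A unchanged if symmetric; otherwise binarize(A + A^T)."""
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    diff = (A - A.T).tocoo()
    if diff.nnz == 0 or np.allclose(diff.data, 0.0):
        return A
    S = sp.csr_array(A + A.T)
    S.data = np.ones_like(S.data)
    return S


def _degrees(A: sp.csr_array) -> np.ndarray:
    return np.asarray(A.sum(axis=1)).ravel()


def combinatorial_laplacian(A) -> sp.csr_array:
    """L = D - A with D the diagonal (weighted) degree matrix; directed input
    is symmetrized first.  Every row sums to zero."""
    A = _symmetrize(_as_sparse(A))
    d = _degrees(A)
    return sp.csr_array(sp.diags_array(d) - A)


def rw_normalized_laplacian(A) -> sp.csr_array:
    """L_rw = I - D^+ A with D^+ the pseudo-inverse degree matrix: rows of
    zero-degree nodes are identically zero."""
    A = _symmetrize(_as_sparse(A))
    d = _degrees(A)
    pos = d > 0
    dinv = np.where(pos, 1.0 / np.where(pos, d, 1.0), 0.0)
    return sp.csr_array(sp.diags_array(pos.astype(float)) - sp.diags_array(dinv) @ A)


def sym_normalized_laplacian(A) -> sp.csr_array:
    """L_sym = I - D^{-1/2} A D^{-1/2}, same zero-degree convention as
    :func:`rw_normalized_laplacian`; symmetric."""
    A = _symmetrize(_as_sparse(A))
    d = _degrees(A)
    pos = d > 0
    dh = np.where(pos, 1.0 / np.sqrt(np.where(pos, d, 1.0)), 0.0)
    Dh = sp.diags_array(dh)
    return sp.csr_array(sp.diags_array(pos.astype(float)) - Dh @ A @ Dh)


def _component_count(A: sp.csr_array) -> int:
    return int(connected_components(A, directed=False)[0])


def fiedler_rw(A, tol: float = DEFAULT_TOL) -> SpectralResult:
    """Second-smallest eigenpair (alpha, mu) of the random-walk normalized
    Laplacian of ``A``.

    Solves the symmetric form and back-transforms ``mu = D^{-1/2} v``,
    renormalized to unit norm with canonical sign.  A shift-invert sparse
    eigensolver handles large inputs; a dense eigendecomposition is used below
    ``DENSE_THRESHOLD`` nodes.
    """
    A = _symmetrize(_as_sparse(A))
    N = A.shape[0]
    if N < 2:
        raise ValueError("need at least 2 nodes for a Fiedler pair")
    d = _degrees(A)
    Lsym = sym_normalized_laplacian(A)

    if N < DENSE_THRESHOLD:
        vals, vecs = scipy.linalg.eigh(Lsym.toarray())
        alpha, v = float(vals[1]), vecs[:, 1]
    else:
        v0 = np.full(N, 1.0 / np.sqrt(N))  # fixed start vector: determinism
        try:
            vals, vecs = spla.eigsh(
                Lsym, k=2, sigma=-0.01, which="LM",
                tol=tol, maxiter=MAX_ITER_FACTOR * N, v0=v0,
            )
        except (spla.ArpackNoConvergence, RuntimeError) as exc:
            raise RuntimeError(
                f"sparse eigensolver failed to converge on N={N}: {exc}"
            ) from exc
        order = np.argsort(vals)
        alpha, v = float(vals[order[1]]), vecs[:, order[1]]

    pos = d > 0
    dh = np.where(pos, 1.0 / np.sqrt(np.where(pos, d, 1.0)), 0.0)
    mu = dh * v
    norm = np.linalg.norm(mu)
    if norm == 0.0:
        # the second eigenvector lived on isolated nodes only; keep v itself
        mu = v.copy()
        norm = np.linalg.norm(mu)
    mu = mu / norm
    mu = _canonical_sign(mu)

    omega = _component_count(A)
    if omega > 1:
        logger.debug("graph has %d components; Fiedler value is ~0", omega)
    return SpectralResult(alpha=alpha, mu=mu, tolerance=tol, zero_multiplicity=omega)


def _canonical_sign(v: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > eps)
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def zero_multiplicity(A, tol: float = DEFAULT_TOL) -> int:
    """Multiplicity of the zero eigenvalue of L_rw, cross-checked against the
    graph-traversal component count (authoritative).

    Raises if the spectral count disagrees with the traversal count, which
    would signal a solver or convention bug.
    """
    A = _symmetrize(_as_sparse(A))
    omega_traversal = _component_count(A)
    N = A.shape[0]
    Lsym = sym_normalized_laplacian(A)
    if N <= 2000:
        vals = scipy.linalg.eigvalsh(Lsym.toarray())
        omega_spectral = int(np.count_nonzero(vals < max(tol, 1e-10) * 100))
    else:
        k = min(omega_traversal + 2, N - 1)
        vals = spla.eigsh(Lsym, k=k, sigma=-0.01, which="LM",
                          return_eigenvectors=False)
        omega_spectral = int(np.count_nonzero(vals < max(tol, 1e-10) * 100))
    if omega_spectral != omega_traversal:
        raise RuntimeError(
            f"zero-eigenvalue multiplicity {omega_spectral} disagrees with "
            f"component count {omega_traversal}"
        )
    return omega_traversal
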