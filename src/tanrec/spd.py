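"""Riemannian numerics on the symmetric positive-definite (SPD) manifold.

Regularized functional connectomes (region-by-region Pearson correlation
matrices) are SPD and live on a curved manifold under the affine-invariant
Riemannian metric (AIRM).  This module provides the calculus needed to work
with them:

* diagonal regularization (``regularize``), the explicit analysis step that
  lifts a rank-deficient correlation matrix back onto the manifold;
* spectral matrix functions (``matrix_function``): log, sqrt, inverse sqrt;
* the AIRM geodesic distance ``d_G(A, B) = ||logm(A^{-1/2} B A^{-1/2})||_F``;
* tangent-space projection at a reference point,
  ``S_hat = logm(C_ref^{-1/2} S C_ref^{-1/2})``, and its inverse retraction;
* the Riemann (Karcher/Frechet) mean, the SPD matrix minimizing the sum of
  squared geodesic distances to a set, computed by fixed-point iteration.

Every matrix function goes through a symmetric eigendecomposition and every
recomposition is explicitly re-symmetrized (``(X + X^T) / 2``), which bounds
floating-point asymmetry drift across chained operations.  Eigenvalues are
never clipped: a singular input is surfaced as an error naming the offending
eigenvalue, and the caller must regularize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymmetricMatrix",
    "SPDMatrix",
    "TangentMatrix",
    "NotSPDError",
    "ConvergenceError",
    "regularize",
    "matrix_function",
    "geodesic_distance",
    "tangent_project",
    "tangent_project_many",
    "tangent_retract",
    "riemann_mean",
    "save_matrix",
    "load_matrix",
]

#: relative tolerance for the symmetry invariant max|A - A^T| <= tol * max|A|
SYMMETRY_RTOL = 1e-10

#: an eigenvalue is treated as nonpositive if it is <= SPD_RTOL * lambda_max
SPD_RTOL = 1e-12


class NotSPDError(ValueError):
    """Input is not symmetric positive-definite."""


class ConvergenceError(RuntimeError):
    """Karcher-mean fixed point did not converge; carries the last gradient norm."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(message)
        self.gradient_norm = gradient_norm


def _as_symmetric(values, name: str = "matrix") -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    scale = float(np.abs(a).max()) if a.size else 0.0
    if scale > 0.0 and float(np.abs(a - a.T).max()) > SYMMETRY_RTOL * scale:
        raise ValueError(
            f"{name} is not symmetric: max|A - A^T| = {np.abs(a - a.T).max():.3e} "
            f"exceeds {SYMMETRY_RTOL:.0e} * max|A| = {SYMMETRY_RTOL * scale:.3e}"
        )
    return 0.5 * (a + a.T)


@dataclass
class SymmetricMatrix:
    """A real symmetric p x p matrix (e.g., a matrix-logarithm output)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = _as_symmetric(self.values, "SymmetricMatrix.values")

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class SPDMatrix:
    """A symmetric positive-definite matrix on the manifold.

    Positive-definiteness is checked at construction: the smallest eigenvalue
    must exceed ``SPD_RTOL`` times the largest.  Regularized functional
    connectomes and Riemann-mean references are represented this way.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = _as_symmetric(self.values, "SPDMatrix.values")
        w = np.linalg.eigvalsh(self.values)
        lo, hi = float(w[0]), float(w[-1])
        if hi <= 0.0 or lo <= SPD_RTOL * hi:
            raise NotSPDError(
                f"matrix {self.label!r} is not positive definite: smallest "
                f"eigenvalue {lo:.6e} (largest {hi:.6e}); regularize first"
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class TangentMatrix:
    """A tangent-space image of an SPD matrix at a reference ``C_ref``.

    ``reference_id`` records which reference the projection used; distances
    between tangent matrices from different references are meaningless and
    are refused downstream.
    """

    values: np.ndarray
    reference_id: str = ""
    label: str = ""

    def __post_init__(self):
        self.values = _as_symmetric(self.values, "TangentMatrix.values")

    @property
    def p(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# internal spectral helpers (array in, array out)
# ---------------------------------------------------------------------------


def _values_of(m) -> np.ndarray:
    return m.values if hasattr(m, "values") else np.asarray(m, dtype=float)


def _eigh(a: np.ndarray):
    return np.linalg.eigh(0.5 * (a + a.T))


_FUNCS = {
    "log": np.log,
    "sqrt": np.sqrt,
    "inv_sqrt": lambda w: 1.0 / np.sqrt(w),
    "exp": np.exp,
}

_NEEDS_POSITIVE = {"log", "sqrt", "inv_sqrt"}


def _spectral(a: np.ndarray, fn: str) -> np.ndarray:
    w, q = _eigh(a)
    if fn in _NEEDS_POSITIVE:
        hi = float(w[-1])
        if hi <= 0.0 or float(w[0]) <= SPD_RTOL * max(hi, 0.0):
            raise NotSPDError(
                f"matrix function {fn!r} needs positive eigenvalues; smallest "
                f"is {w[0]:.6e} (largest {hi:.6e}); not clipping — regularize"
            )
    out = (q * _FUNCS[fn](w)) @ q.T
    return 0.5 * (out + out.T)


def _logm(a):
    return _spectral(a, "log")


def _expm(a):
    return _spectral(a, "exp")


def _sqrtm(a):
    return _spectral(a, "sqrt")


def _invsqrtm(a):
    return _spectral(a, "inv_sqrt")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def regularize(C, lam: float, label: str | None = None) -> SPDMatrix:
    """Increment the main diagonal of a symmetric PSD matrix by ``lam``.

    This is the explicit regularization step that makes a singular correlation
    matrix positive definite: every eigenvalue is shifted by exactly ``lam``.

    Parameters
    ----------
    C : array-like or matrix object with ``.values``
        Symmetric positive-semidefinite input (e.g., a raw FC).
    lam : float
        Nonnegative diagonal increment.  ``lam = 0`` leaves ``C`` unchanged
        and therefore fails loudly if ``C`` is singular.

    Raises
    ------
    NotSPDError
        If the shifted matrix is still not positive definite; the message
        names the offending smallest eigenvalue.
    """
    lam = float(lam)
    if lam < 0.0:
        raise ValueError(f"regularization value must be nonnegative, got {lam}")
    a = _as_symmetric(_values_of(C), "regularize input")
    out = a + lam * np.eye(a.shape[0])
    if label is None:
        label = getattr(C, "label", "") or ""
    try:
        return SPDMatrix(out, label=label)
    except NotSPDError:
        w0 = float(np.linalg.eigvalsh(a)[0])
        raise NotSPDError(
            f"regularize(lam={lam:g}) did not reach positive definiteness: "
            f"input smallest eigenvalue {w0:.6e}; increase the regularization value"
        ) from None


def matrix_function(S, fn: str) -> SymmetricMatrix:
    """Apply ``log``, ``sqrt`` or ``inv_sqrt`` to an SPD matrix spectrally.

    Eigendecompose ``S = Q diag(w) Q^T``, apply ``fn`` to the eigenvalues and
    recompose with forced symmetrization.  Nonpositive eigenvalues raise
    :class:`NotSPDError` — they are never clipped.
    """
    if fn not in ("log", "sqrt", "inv_sqrt"):
        raise ValueError(f"fn must be one of log, sqrt, inv_sqrt; got {fn!r}")
    a = _as_symmetric(_values_of(S), "matrix_function input")
    return SymmetricMatrix(_spectral(a, fn), label=f"{fn}({getattr(S, 'label', '')})")


def geodesic_distance(A, B) -> float:
    """AIRM (geodesic) distance ``||logm(A^{-1/2} B A^{-1/2})||_F``.

    Equals ``sqrt(sum_i ln^2 lambda_i)`` over the eigenvalues of ``A^{-1} B``;
    symmetric in its arguments and affine-invariant.
    """
    a = _as_symmetric(_values_of(A), "geodesic_distance A")
    b = _as_symmetric(_values_of(B), "geodesic_distance B")
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    r = _invsqrtm(a)
    inner = r @ b @ r
    return float(np.linalg.norm(_logm(inner), "fro"))


def tangent_project(S, C_ref, reference_id: str | None = None) -> TangentMatrix:
    """Project an SPD matrix onto the tangent space at ``C_ref``.

    ``S_hat = logm(C_ref^{-1/2} S C_ref^{-1/2})``, explicitly symmetrized.
    Projecting the reference itself yields the zero matrix.
    """
    a = _as_symmetric(_values_of(S), "tangent_project S")
    ref = _as_symmetric(_values_of(C_ref), "tangent_project C_ref")
    if a.shape != ref.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {ref.shape}")
    r = _invsqrtm(ref)
    t = _logm(r @ a @ r)
    if reference_id is None:
        reference_id = getattr(C_ref, "label", "") or "C_ref"
    return TangentMatrix(t, reference_id=reference_id, label=getattr(S, "label", ""))


def tangent_project_many(S_list, C_ref, reference_id: str | None = None):
    """Project many SPD matrices at the same reference, factorizing the
    reference inverse square root once."""
    ref = _as_symmetric(_values_of(C_ref), "tangent_project C_ref")
    r = _invsqrtm(ref)
    if reference_id is None:
        reference_id = getattr(C_ref, "label", "") or "C_ref"
    out = []
    for S in S_list:
        a = _as_symmetric(_values_of(S), "tangent_project S")
        if a.shape != ref.shape:
            raise ValueError(f"dimension mismatch: {a.shape} vs {ref.shape}")
        out.append(
            TangentMatrix(
                _logm(r @ a @ r),
                reference_id=reference_id,
                label=getattr(S, "label", ""),
            )
        )
    return out


def tangent_retract(T, C_ref) -> SPDMatrix:
    """Inverse of :func:`tangent_project`:
    ``C_ref^{1/2} expm(T) C_ref^{1/2}``."""
    t = _as_symmetric(_values_of(T), "tangent_retract T")
    ref = _as_symmetric(_values_of(C_ref), "tangent_retract C_ref")
    if t.shape != ref.shape:
        raise ValueError(f"dimension mismatch: {t.shape} vs {ref.shape}")
    h = _sqrtm(ref)
    out = h @ _expm(t) @ h
    return SPDMatrix(0.5 * (out + out.T), label=getattr(T, "label", ""))


def riemann_mean(
    S_list,
    init="arithmetic",
    tol: float = 1e-8,
    max_iter: int = 200,
    label: str = "riemann_mean",
) -> SPDMatrix:
    """Riemann (Karcher) mean of a set of SPD matrices.

    The mean is the SPD matrix minimizing the sum of squared geodesic
    distances to the set.  It is found by the standard fixed-point iteration:
    at the current estimate ``C``, the mean tangent vector
    ``M = (1/n) sum_i logm(C^{-1/2} S_i C^{-1/2})`` is the (negative,
    rescaled) Riemannian gradient; the update is
    ``C <- C^{1/2} expm(M) C^{1/2}`` (unit step), stopping when
    ``||M||_F < tol``.

    Parameters
    ----------
    S_list : sequence of SPD matrices (objects or arrays)
    init : "arithmetic" or an SPD matrix
        Starting point; the arithmetic mean is the conventional choice.
    tol : float
        Convergence threshold on the gradient Frobenius norm.
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`
        carrying the last gradient norm.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    arrays = [_as_symmetric(_values_of(s), "riemann_mean element") for s in S_list]
    if not arrays:
        raise ValueError("riemann_mean needs a nonempty list")
    p = arrays[0].shape[0]
    for a in arrays:
        if a.shape[0] != p:
            raise ValueError("riemann_mean elements must share dimensions")
    stack = np.stack(arrays)
    if isinstance(init, str):
        if init != "arithmetic":
            raise ValueError(f"unknown init {init!r}")
        c = stack.mean(axis=0)
    else:
        c = _as_symmetric(_values_of(init), "riemann_mean init")
    gnorm = np.inf
    for _ in range(max_iter):
        w, q = _eigh(c)
        if w[0] <= SPD_RTOL * max(w[-1], 0.0):
            raise NotSPDError(
                f"Karcher iterate lost positive definiteness (eigenvalue {w[0]:.3e})"
            )
        r_inv = (q / np.sqrt(w)) @ q.T
        r_half = (q * np.sqrt(w)) @ q.T
        m = np.zeros_like(c)
        for a in stack:
            m += _logm(r_inv @ a @ r_inv)
        m /= len(stack)
        gnorm = float(np.linalg.norm(m, "fro"))
        if gnorm < tol:
            return SPDMatrix(c, label=label)
        c = r_half @ _expm(m) @ r_half
        c = 0.5 * (c + c.T)
    raise ConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last gradient norm {gnorm:.3e})",
        gradient_norm=gnorm,
    )


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------


def save_matrix(path, M, labels=None) -> None:
    """Write a matrix as TSV at 17 significant digits (bit-stable round trip).

    An optional header row carries region labels.
    """
    a = np.atleast_2d(np.asarray(_values_of(M), dtype=float))
    with open(path, "w") as fh:
        if labels is not None:
            if len(labels) != a.shape[1]:
                raise ValueError("label count does not match column count")
            fh.write("\t".join(str(x) for x in labels) + "\n")
        for row in a:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def load_matrix(path):
    """Read a TSV matrix written by :func:`save_matrix`.

    Returns ``(values, labels)`` where ``labels`` is ``None`` when no header
    row is present.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path} is empty")
    first = lines[0].split("\t")
    labels = None
    try:
        [float(x) for x in first]
    except ValueError:
        labels = first
        lines = lines[1:]
    values = np.array([[float(x) for x in ln.split("\t")] for ln in lines])
    return values, labels
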