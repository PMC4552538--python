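"""Discrete Laguerre and Meixner basis dictionaries for kernel expansion.

Impulse responses of autonomic mechanisms decay over tens of seconds, so we
expand each kernel on a small set of orthonormal, exponentially decaying
discrete functions instead of estimating every lag freely.  Two families are
provided:

* **Discrete Laguerre functions** ``phi_j``: generated by repeatedly passing
  the geometric seed ``sqrt(1 - a^2) * a^n`` through the all-pass section
  ``(z^-1 - a) / (1 - a z^-1)``, where ``a`` (the *pole*) sets the decay rate.
* **Meixner functions**: a generalization indexed by an integer *order of
  generalization* ``j``.  They are the orthonormal functions associated with
  the negative-binomial weight ``w(x) = C(x + j, j) * a^(2x)``; for ``j = 0``
  the weight is geometric and the family reduces exactly to the Laguerre
  functions.  Increasing ``j`` multiplies the weight by a polynomially
  growing factor, which delays the initial rise of every basis function —
  useful for mechanisms whose impulse responses start slowly (e.g. the
  sympathetically mediated vascular branches).

Dictionaries are constructed on an extended support long enough for the
functions to decay, truncated to the model memory (50 lags at 0.5 s), and
re-orthonormalized by a triangular (span- and sign-preserving) transform so
that the truncated columns form an exactly orthonormal set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .branches import MEMORY

__all__ = ["BasisDictionary", "laguerre_basis", "meixner_basis"]

#: re-orthonormalization is silent below this Gram-matrix drift
_DRIFT_WARN = 1e-6


@dataclass
class BasisDictionary:
    """An orthonormal dictionary of decaying discrete functions.

    ``matrix`` has shape ``(memory, n_funcs)``; column ``k`` is the k-th basis
    function evaluated at lags ``0 .. memory-1``.
    """

    pole: float
    gen_order: int
    n_funcs: int
    memory: int
    matrix: np.ndarray
    truncation_drift: float = field(default=0.0)

    def project(self, kernel: np.ndarray) -> np.ndarray:
        """Expansion coefficients of ``kernel`` on the dictionary columns."""
        kernel = np.asarray(kernel, dtype=float)
        if kernel.shape != (self.memory,):
            raise ValueError(f"kernel must have length {self.memory}")
        return self.matrix.T @ kernel

    def reconstruct(self, coeffs: np.ndarray) -> np.ndarray:
        """Kernel represented by expansion coefficients ``coeffs``."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.n_funcs,):
            raise ValueError(f"need {self.n_funcs} coefficients")
        return self.matrix @ coeffs

    def gram(self) -> np.ndarray:
        return self.matrix.T @ self.matrix


def _check_args(pole: float, gen_order: int, n_funcs: int, memory: int) -> None:
    if not (0.0 <= pole < 1.0):
        raise ValueError(f"pole must lie in [0, 1), got {pole:g}")
    if gen_order < 0:
        raise ValueError("order of generalization must be >= 0")
    if n_funcs < 1:
        raise ValueError("need at least one basis function")
    if n_funcs > memory:
        raise ValueError(f"n_funcs ({n_funcs}) cannot exceed memory ({memory})")
    if gen_order > 0 and pole == 0.0:
        raise ValueError("generalization orders >= 1 require a strictly positive pole")


def _support_length(pole: float, gen_order: int, memory: int) -> int:
    """Support long enough that the weight's tail is at machine-precision level."""
    if pole == 0.0:
        return memory
    # geometric decay a^(2x) beats the polynomial factor x^gen_order eventually;
    # add a generous polynomial margin.
    n_geo = int(np.ceil(np.log(1e-18) / (2.0 * np.log(pole))))
    return max(memory, n_geo + 25 * (gen_order + 1))


def _truncate_reorthonormalize(full: np.ndarray, memory: int) -> tuple[np.ndarray, float]:
    """Truncate to ``memory`` lags and restore exact column orthonormality.

    Uses the Cholesky factor of the truncated Gram matrix, a triangular
    transform: it keeps the nested span (function k only mixes with functions
    0..k) and the sign of each function's new component.
    """
    trunc = full[:memory, :]
    gram = trunc.T @ trunc
    drift = float(np.max(np.abs(gram - np.eye(gram.shape[0]))))
    if drift > _DRIFT_WARN:
        warnings.warn(
            f"basis truncation drift {drift:.2e} exceeds {_DRIFT_WARN:g}; "
            "columns re-orthonormalized over the truncated support",
            stacklevel=3,
        )
    chol = np.linalg.cholesky(gram)
    out = np.linalg.solve(chol, trunc.T).T
    return out, drift


def _laguerre_full(pole: float, n_funcs: int, support: int) -> np.ndarray:
    """Laguerre functions on ``support`` lags via the stable all-pass recurrence."""
    a = pole
    full = np.zeros((support, n_funcs))
    n = np.arange(support)
    if a == 0.0:
        return np.eye(support, n_funcs)
    full[:, 0] = np.sqrt(1.0 - a * a) * a**n
    for j in range(1, n_funcs):
        prev = full[:, j - 1]
        cur = full[:, j]
        cur[0] = -a * prev[0]
        for i in range(1, support):
            cur[i] = a * cur[i - 1] + prev[i - 1] - a * prev[i]
    return full


def laguerre_basis(pole: float, n_funcs: int, memory: int = MEMORY) -> BasisDictionary:
    """Discrete Laguerre dictionary (order of generalization 0).

    ``pole = 0`` degenerates to the impulse dictionary: function ``j`` is the
    unit impulse at lag ``j``.
    """
    _check_args(pole, 0, n_funcs, memory)
    support = _support_length(pole, 0, memory)
    full = _laguerre_full(pole, n_funcs, support)
    mat, drift = _truncate_reorthonormalize(full, memory)
    return BasisDictionary(pole, 0, n_funcs, memory, mat, drift)


def _meixner_full(pole: float, gen_order: int, n_funcs: int, support: int) -> np.ndarray:
    """Meixner functions via orthonormal polynomials of the generalized weight.

    Column k is ``sqrt(w(x)) * q_k(x)`` with ``q_k`` the degree-k orthonormal
    polynomial for ``w(x) = C(x + j, j) * pole^(2x)``.  The orthonormal
    polynomial sequence is computed by QR factorization of a scaled weighted
    Vandermonde matrix; the positive-diagonal convention fixes signs so that
    ``sign(q_k(0)) = (-1)^k``, matching the Laguerre recurrence at ``j = 0``.
    """
    a = pole
    x = np.arange(support, dtype=float)
    j = gen_order
    log_w = gammaln(x + j + 1) - gammaln(x + 1) - gammaln(j + 1) + 2.0 * x * np.log(a)
    sqrt_w = np.exp(0.5 * log_w)
    # scale the polynomial variable so the Vandermonde columns stay O(1)
    t = x * (1.0 - a)
    vand = sqrt_w[:, None] * t[:, None] ** np.arange(n_funcs)[None, :]
    vand /= np.linalg.norm(vand, axis=0, keepdims=True)
    q, r = np.linalg.qr(vand)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs[None, :]


def meixner_basis(
    pole: float, gen_order: int, n_funcs: int, memory: int = MEMORY
) -> BasisDictionary:
    """Meixner dictionary with the given order of generalization.

    ``gen_order = 0`` returns exactly the discrete Laguerre dictionary.
    Higher orders rise more slowly from lag 0 (the leading function's value at
    lag 0 is ``(1 - pole^2)^((gen_order + 1) / 2)``, decreasing in the order).
    """
    _check_args(pole, gen_order, n_funcs, memory)
    if gen_order == 0:
        return laguerre_basis(pole, n_funcs, memory)
    support = _support_length(pole, gen_order, memory)
    full = _meixner_full(pole, gen_order, n_funcs, support)
    mat, drift = _truncate_reorthonormalize(full, memory)
    return BasisDictionary(pole, gen_order, n_funcs, memory, mat, drift)
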