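"""Fitness calculus of Fisher's geometric model.

A cell phenotype is a point ``z`` in an n-dimensional Euclidean trait
space; fitness is a Gaussian function of the displacement from a
phenotypic optimum ``z_opt``, shaped by a symmetric positive-definite
selection matrix ``S``:

    w(z) = exp(-(z - z_opt)^T S^-1 (z - z_opt))

The isotropic case ``S = sigma2 * I`` gives the classical single-intensity
landscape ``w(d) = exp(-d^2 / sigma2)`` with ``d`` the Euclidean distance
to the optimum.  Mutations displace the phenotype by a draw from a
multivariate normal with mean 0 and covariance ``M``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionMatrix",
    "MutationEffect",
    "as_phenotype",
    "evaluate_fitness",
    "selection_coefficient",
    "sample_mutation",
    "landscape_width",
    "phenotype_from_fitness",
    "mvn_factor",
]

_SYM_TOL = 1e-12


def as_phenotype(values, n: int | None = None) -> np.ndarray:
    """Validate and return a phenotype as a 1-D float array.

    Raises ``ValueError`` on non-finite entries or a dimension mismatch
    with ``n`` when given.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("phenotype must be a 1-D vector with n >= 1 traits")
    if not np.all(np.isfinite(z)):
        raise ValueError("phenotype entries must be finite")
    if n is not None and z.size != n:
        raise ValueError(f"phenotype has {z.size} traits, expected {n}")
    return z


@dataclass(frozen=True)
class SelectionMatrix:
    """Symmetric positive-definite selection matrix S.

    ``S`` sets the shape (width along each trait combination) of the
    fitness peak; its inverse is cached for the quadratic form.
    """

    entries: np.ndarray
    _inv: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        S = np.asarray(self.entries, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("selection matrix must be square")
        if not np.all(np.isfinite(S)):
            raise ValueError("selection matrix entries must be finite")
        scale = max(1.0, float(np.abs(S).max()))
        if np.abs(S - S.T).max() > _SYM_TOL * scale:
            raise ValueError("selection matrix must be symmetric")
        S = 0.5 * (S + S.T)
        eigvals = np.linalg.eigvalsh(S)
        if eigvals.min() <= 0:
            raise ValueError("selection matrix must be positive definite")
        object.__setattr__(self, "entries", S)
        object.__setattr__(self, "_inv", np.linalg.inv(S))

    @classmethod
    def isotropic(cls, sigma2: float, n: int) -> "SelectionMatrix":
        """Isotropic landscape S = sigma2 * I (universal pleiotropy)."""
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        return cls(sigma2 * np.eye(n))

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        return self._inv

    @property
    def width(self) -> float:
        """Geometric-mean eigenvalue width, det(S)^(1/n)."""
        return landscape_width(self)

    def quadratic_form(self, dz: np.ndarray) -> np.ndarray:
        """(dz)^T S^-1 (dz) for one displacement or a (m, n) batch."""
        dz = np.asarray(dz, dtype=float)
        if dz.shape[-1] != self.n:
            raise ValueError("displacement dimension does not match S")
        return np.einsum("...i,ij,...j->...", dz, self._inv, dz)


@dataclass(frozen=True)
class MutationEffect:
    """Phenotypic displacement r of a mutation and its size ||r||."""

    displacement: np.ndarray

    def __post_init__(self):
        r = as_phenotype(self.displacement)
        object.__setattr__(self, "displacement", r)

    @property
    def size(self) -> float:
        return float(np.linalg.norm(self.displacement))


def _coerce_S(S) -> SelectionMatrix:
    return S if isinstance(S, SelectionMatrix) else SelectionMatrix(S)


def evaluate_fitness(z, z_opt, S) -> float:
    """Gaussian fitness of phenotype ``z`` against optimum ``z_opt``.

    Returns a value in (0, 1]; exactly 1 iff ``z == z_opt``.  Fitness that
    underflows the double range is returned as 0.0, which downstream code
    treats as certain death.
    """
    S = _coerce_S(S)
    z = as_phenotype(z, S.n)
    z_opt = as_phenotype(z_opt, S.n)
    q = float(S.quadratic_form(z - z_opt))
    return float(np.exp(-q))


def selection_coefficient(z, z_mut, z_opt, S) -> float:
    """s = w(z_mut)/w(z) - 1 against a common optimum and S.

    Positive iff the mutant sits strictly closer to the optimum in the
    S^-1 metric.
    """
    w = evaluate_fitness(z, z_opt, S)
    w_mut = evaluate_fitness(z_mut, z_opt, S)
    if w == 0.0:
        raise ValueError("parent fitness underflowed to 0; s is undefined")
    return w_mut / w - 1.0


def mvn_factor(M: np.ndarray) -> np.ndarray:
    """Factor A with A A^T = M for sampling MVN(0, M) as A @ standard normals.

    Accepts any symmetric positive semi-definite M (eigen-decomposition,
    so rank-deficient covariances are fine).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("covariance entries must be finite")
    scale = max(1.0, float(np.abs(M).max()))
    if np.abs(M - M.T).max() > _SYM_TOL * scale:
        raise ValueError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    if vals.min() < -1e-10 * scale:
        raise ValueError("covariance must be positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def sample_mutation(M, rng: np.random.Generator) -> MutationEffect:
    """Draw one mutation effect r ~ MVN(0, M)."""
    A = mvn_factor(M)
    r = A @ rng.standard_normal(A.shape[0])
    return MutationEffect(r)


def landscape_width(S) -> float:
    """Average landscape width: geometric mean of the eigenvalues of S."""
    S = _coerce_S(S)
    sign, logdet = np.linalg.slogdet(S.entries)
    return float(np.exp(logdet / S.n))


def phenotype_from_fitness(w0: float, S, z_opt) -> np.ndarray:
    """Phenotype at predefined fitness ``w0``, displaced along trait 1.

    Inverts the fitness function along the first trait axis:
    ``x^2 (S^-1)_11 = -ln w0``; for isotropic S the displacement is
    ``sqrt(-sigma2 * ln w0)``.
    """
    if not (0.0 < w0 <= 1.0):
        raise ValueError("w0 must lie in (0, 1]")
    S = _coerce_S(S)
    z_opt = as_phenotype(z_opt, S.n)
    x = np.sqrt(-np.log(w0) / S.inverse[0, 0])
    z = z_opt.copy()
    z[0] += x
    return z
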