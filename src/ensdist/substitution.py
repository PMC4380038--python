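"""Rate-matrix algebra and the expected number of substitutions (ENS).

A continuous-time substitution process on the nucleotide alphabet is
specified by a 4x4 generator ``Q`` (rows sum to zero, off-diagonals
nonnegative) and an initial distribution ``f0`` over ``A, C, G, T``.  The
process is *stationary* when ``f0`` equals the equilibrium distribution
``pi`` of ``Q`` and *nonstationary* otherwise.  The expected number of
substitutions accrued over ``[0, t]`` is

    n(t) = -integral_0^t f(s) ds . diag(Q),      f(s) = f0 exp(Qs),

which reduces to ``-sum_i pi_i Q_ii t`` in the stationary case.  ``n(t)``
is the genetic distance reported throughout this package; it is evaluated
exactly through a single matrix exponential of the augmented 5x5 matrix

    C = [[Q, -diag(Q)], [0, 0]],      n(t) = f0 . exp(Ct)[0:4, 4].

State order is fixed as ``A, C, G, T`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import expm
from scipy.optimize import brentq

NUCLEOTIDES = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: indices of the 12 off-diagonal entries, row-major
OFF_DIAGONAL = [(i, j) for i in range(4) for j in range(4) if i != j]

_STRUCT_TOL = 1e-12  # structural invariants (row sums, probability sums)
_ALG_TOL = 1e-10  # algebraic identities (calibration, stationarity)


class ValidationError(ValueError):
    """An input violates a structural invariant."""


def validate_distribution(p, tol: float = _STRUCT_TOL) -> np.ndarray:
    """Validate and return a probability row vector over ``A, C, G, T``."""
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValidationError(f"distribution must have shape (4,), got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError("distribution contains non-finite entries")
    if np.any(p < -tol):
        raise ValidationError("distribution contains negative entries")
    if abs(p.sum() - 1.0) > max(tol, 1e-12):
        raise ValidationError(f"distribution sums to {p.sum()!r}, not 1")
    return np.clip(p, 0.0, None)


def validate_rate_matrix(Q, tol: float = _STRUCT_TOL) -> np.ndarray:
    """Validate a generator: zero row sums, nonnegative off-diagonals."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValidationError(f"rate matrix must be 4x4, got {Q.shape}")
    if not np.all(np.isfinite(Q)):
        raise ValidationError("rate matrix contains non-finite entries")
    off = Q[tuple(zip(*OFF_DIAGONAL))]
    if np.any(off < -tol):
        raise ValidationError("rate matrix has negative off-diagonal entries")
    if np.max(np.abs(Q.sum(axis=1))) > max(tol, 1e-9 * max(1.0, np.abs(Q).max())):
        raise ValidationError("rate matrix rows do not sum to zero")
    return Q


def validate_transition_matrix(P, tol: float = _ALG_TOL) -> np.ndarray:
    """Validate a stochastic matrix: entries in [0, 1], unit row sums."""
    P = np.asarray(P, dtype=float)
    if P.shape != (4, 4):
        raise ValidationError(f"transition matrix must be 4x4, got {P.shape}")
    if np.any(P < -_STRUCT_TOL) or np.any(P > 1 + _STRUCT_TOL):
        raise ValidationError("transition matrix entries outside [0, 1]")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > tol:
        raise ValidationError("transition matrix rows do not sum to one")
    return P


def make_rate_matrix(off_diagonals) -> np.ndarray:
    """Build a generator from its 12 off-diagonal rates (row-major order).

    The diagonal is set so every row sums to zero.  This is the fully
    general time-homogeneous parameterization: one free rate per ordered
    pair of distinct nucleotides.
    """
    off = np.asarray(off_diagonals, dtype=float).ravel()
    if off.shape != (12,):
        raise ValidationError(f"expected 12 off-diagonal rates, got {off.shape}")
    if not np.all(np.isfinite(off)) or np.any(off < 0):
        raise ValidationError("off-diagonal rates must be finite and nonnegative")
    Q = np.zeros((4, 4))
    for (i, j), v in zip(OFF_DIAGONAL, off):
        Q[i, j] = v
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def jc_rate_matrix() -> np.ndarray:
    """Calibrated Jukes-Cantor generator (all off-diagonals 1/3)."""
    return make_rate_matrix(np.full(12, 1.0 / 3.0))


def f81_rate_matrix(pi, alpha: float = 1.0) -> np.ndarray:
    """Felsenstein-1981 generator ``Q_ij = alpha * pi_j`` for ``i != j``."""
    pi = validate_distribution(pi)
    if not alpha > 0:
        raise ValidationError("alpha must be positive")
    Q = alpha * np.tile(pi, (4, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def gtr_rate_matrix(exchangeabilities, pi) -> np.ndarray:
    """Time-reversible generator ``Q_ij = R_ij * pi_j`` with symmetric R.

    ``exchangeabilities`` are the 6 upper-triangular entries of R in the
    order AC, AG, AT, CG, CT, GT.
    """
    r = np.asarray(exchangeabilities, dtype=float).ravel()
    if r.shape != (6,):
        raise ValidationError("expected 6 exchangeability parameters")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValidationError("exchangeabilities must be finite and nonnegative")
    pi = validate_distribution(pi)
    R = np.zeros((4, 4))
    R[np.triu_indices(4, 1)] = r
    R = R + R.T
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q) -> np.ndarray:
    """The unique probability row vector ``pi`` with ``pi Q = 0``.

    Solved as a bordered linear system; raises if the generator does not
    admit a unique stationary distribution (reducible or defective input).
    """
    Q = validate_rate_matrix(Q)
    # Append the normalization constraint to pi Q = 0 and solve by least
    # squares; uniqueness requires rank 4 of the stacked system.
    A = np.vstack([Q.T, np.ones((1, 4))])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValidationError("generator has no unique stationary distribution")
    if np.linalg.norm(pi @ Q, np.inf) > _ALG_TOL or np.any(pi < -_ALG_TOL):
        raise ValidationError("failed to solve for a valid stationary distribution")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def substitution_rate(Q, freqs=None) -> float:
    """Expected substitutions per unit time: ``-sum_i f_i Q_ii``.

    ``freqs`` defaults to the stationary distribution of ``Q``.
    """
    Q = validate_rate_matrix(Q)
    f = stationary_distribution(Q) if freqs is None else validate_distribution(freqs)
    return float(-f @ np.diag(Q))


def calibrate(Q, freqs=None) -> np.ndarray:
    """Rescale ``Q`` so the expected substitution rate at ``freqs`` is one.

    Under calibration edge durations are expected numbers of substitutions
    at stationarity, which is what makes branch lengths comparable across
    processes.  Calibration is idempotent and scale equivariant.
    """
    rate = substitution_rate(Q, freqs)
    if rate <= 0:
        raise ValidationError("cannot calibrate a generator with zero total rate")
    return np.asarray(Q, dtype=float) / rate


def is_calibrated(Q, freqs=None, tol: float = _ALG_TOL) -> bool:
    return abs(substitution_rate(Q, freqs) - 1.0) <= tol


@dataclass(frozen=True)
class EdgeProcess:
    """One edge's substitution process: a generator and a duration.

    Only the product ``Q * t`` is identifiable from data on the edge's
    endpoints, so fitted General-model edges carry the scaled generator
    with ``t = 1``.
    """

    rate_matrix: np.ndarray
    duration: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "rate_matrix", validate_rate_matrix(self.rate_matrix))
        if not (np.isfinite(self.duration) and self.duration >= 0):
            raise ValidationError("edge duration must be finite and nonnegative")

    @property
    def scaled(self) -> np.ndarray:
        """The identifiable product ``Q * t``."""
        return self.rate_matrix * self.duration

    def transition_matrix(self, rate: float = 1.0) -> np.ndarray:
        return transition_matrix(self.rate_matrix, self.duration * rate)

    def ens(self, f0) -> float:
        return ens(f0, self.rate_matrix, self.duration)


def transition_matrix(Q, t: float) -> np.ndarray:
    """``P(t) = exp(Qt)`` via scaling-and-squaring (robust for defective Q)."""
    Q = np.asarray(Q, dtype=float)
    if t < 0:
        raise ValidationError("duration must be nonnegative")
    if t == 0:
        return np.eye(4)
    P = expm(Q * t)
    # exp of a generator is stochastic up to roundoff; clip tiny negatives
    return np.clip(P, 0.0, None)


def _augmented(Q: np.ndarray) -> np.ndarray:
    C = np.zeros((5, 5))
    C[:4, :4] = Q
    C[:4, 4] = -np.diag(Q)
    return C


def ens(f0, Q, t: float = 1.0) -> float:
    """Expected number of substitutions over ``[0, t]`` from initial ``f0``.

    Exact evaluation of the ENS integral through one matrix exponential of
    the augmented 5x5 matrix ``[[Q, -diag(Q)], [0, 0]]``; the last column of
    ``exp(Ct)`` holds the per-state integrated substitution rates.
    """
    f0 = validate_distribution(f0)
    Q = validate_rate_matrix(Q)
    if t < 0:
        raise ValidationError("duration must be nonnegative")
    if t == 0:
        return 0.0
    return float(f0 @ expm(_augmented(Q) * t)[:4, 4])


def ens_quadrature(f0, Q, t: float, n_steps: int = 10_000) -> float:
    """Direct numerical integration of the ENS integral (test oracle).

    Evaluates ``-f(s) . diag(Q)`` on a uniform grid by stepwise exact
    propagation of ``f`` and integrates with Simpson's rule.  Kept
    deliberately independent of :func:`ens`.
    """
    f0 = validate_distribution(f0)
    Q = validate_rate_matrix(Q)
    if n_steps < 100:
        raise ValidationError("n_steps must be at least 100")
    if t == 0:
        return 0.0
    grid = np.linspace(0.0, t, n_steps + 1)
    step = expm(Q * (t / n_steps))
    f = np.empty((n_steps + 1, 4))
    f[0] = f0
    for k in range(n_steps):
        f[k + 1] = f[k] @ step
    integrand = -(f @ np.diag(Q))
    return float(simpson(integrand, x=grid))


def ens_stationary(pi, Q, t: float) -> float:
    """Stationary-case ENS: ``-sum_i pi_i Q_ii t`` (linear in ``t``)."""
    pi = validate_distribution(pi)
    Q = validate_rate_matrix(Q)
    return float(-pi @ np.diag(Q) * t)


def f81_closed_form_ens(pi, alpha: float, t: float, f0) -> float:
    """Closed-form ENS for the Felsenstein-1981 process.

    With ``f_i(s) = pi_i + (f_i(0) - pi_i) e^{-alpha s}`` the ENS integral
    evaluates to

        n(t) = alpha t sum_i pi_i (1 - pi_i)
               + (1 - e^{-alpha t}) sum_i (1 - pi_i)(f_i(0) - pi_i).

    The correction term vanishes for uniform ``pi`` regardless of ``f0``
    and for a stationary start ``f0 = pi``; otherwise it can take either
    sign, so a stationary analysis may over- or understate the distance.
    """
    pi = validate_distribution(pi)
    f0 = validate_distribution(f0)
    if not alpha > 0:
        raise ValidationError("alpha must be positive")
    stationary_term = alpha * t * np.sum(pi * (1.0 - pi))
    correction = (1.0 - np.exp(-alpha * t)) * np.sum((1.0 - pi) * (f0 - pi))
    return float(stationary_term + correction)


@dataclass
class _ScaledEnsProfile:
    """Cheap evaluator for ``s -> ens(f0, A, s)`` for a fixed direction ``A``.

    Diagonalizes ``A`` once so that the ENS integral has the closed form
    ``sum_k c_k w_k phi(lambda_k, s)`` with ``phi = (e^{ls} - 1)/l``; falls
    back to the augmented matrix exponential when ``A`` is numerically
    defective.  Used by the clock-constrained fits and by the simulator,
    where the same direction is rescaled many times.
    """

    f0: np.ndarray
    A: np.ndarray
    _use_eig: bool = field(init=False)
    _cw: np.ndarray = field(init=False, default=None)
    _lam: np.ndarray = field(init=False, default=None)

    def __post_init__(self):
        self.f0 = validate_distribution(self.f0)
        self.A = validate_rate_matrix(self.A)
        lam, V = np.linalg.eig(self.A)
        try:
            cond = np.linalg.cond(V)
        except np.linalg.LinAlgError:  # pragma: no cover - singular V
            cond = np.inf
        self._use_eig = np.isfinite(cond) and cond < 1e8
        if self._use_eig:
            c = self.f0.astype(complex) @ V
            w = np.linalg.solve(V, -np.diag(self.A).astype(complex))
            self._cw = c * w
            self._lam = lam

    def __call__(self, s: float) -> float:
        if s == 0:
            return 0.0
        if not self._use_eig:
            return ens(self.f0, self.A, s)
        z = self._lam * s
        small = np.abs(z) < 1e-8
        phi = np.empty_like(z)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi[~small] = np.expm1(z[~small]) / self._lam[~small]
        # series (e^z - 1)/lam = s (1 + z/2 + z^2/6) for tiny z
        phi[small] = s * (1.0 + z[small] / 2.0 + z[small] ** 2 / 6.0)
        return float(np.real(np.sum(self._cw * phi)))


def solve_ens_duration(f0, A, target: float, xtol: float = 1e-12) -> float:
    """Solve ``ens(f0, A, s) = target`` for the scale ``s >= 0``.

    Valid because ENS is monotonically nondecreasing in the duration (its
    integrand ``-f(s) . diag(A)`` is nonnegative).  Used to impose the
    molecular-clock constraint on a fitted edge.
    """
    if target < 0:
        raise ValidationError("target ENS must be nonnegative")
    if target == 0:
        return 0.0
    profile = _ScaledEnsProfile(f0, A)
    rate0 = float(-np.asarray(f0) @ np.diag(np.asarray(A, dtype=float)))
    if rate0 <= 0:
        raise ValidationError("direction has zero substitution rate at f0")
    hi = max(target / rate0, 1e-6)
    for _ in range(200):
        if profile(hi) >= target:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable for valid generators
        raise ValidationError("failed to bracket the target ENS")
    return float(brentq(lambda s: profile(s) - target, 0.0, hi, xtol=xtol))
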