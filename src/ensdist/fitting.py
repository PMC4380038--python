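"""Maximum-likelihood fitting of triad substitution models.

Three model families are fitted to the 64 site-pattern counts of a triad
alignment, in order of increasing generality:

``GTR``
    one calibrated time-reversible generator ``Q_ij = R_ij pi_j`` shared by
    all three edges, root distribution fixed at its stationary ``pi``, one
    duration per edge.  11 free parameters.
``GTR+Gamma``
    GTR plus Gamma-distributed rate heterogeneity across sites in four
    equal-probability bins (bin-mean discretization), adding the shape
    parameter.  12 free parameters.
``General``
    an unconstrained generator per edge and a free root distribution; the
    most general identifiable time-homogeneous model.  Only the product
    ``A = Q t`` is identifiable per edge, so ``A`` is optimized directly
    (12 off-diagonals per edge, duration fixed at 1).  39 free parameters.

Each family has a *clock* variant constraining the two ingroup edges to
equal length by the ENS distance (one fewer parameter), used by the
relative-rate molecular-clock test.  Fits are seeded sequentially from the
next-simpler model, which guarantees that log-likelihood is nondecreasing
along the nesting chain: the optimizer starts at the simpler model's
optimum and never accepts an increase of the objective.

All positive parameters are optimized on the log scale with L-BFGS-B; the
root distribution uses a softmax parameterization.  The General free fit
uses an analytic gradient (the adjoint Frechet derivative of the matrix
exponential); the remaining fits use finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .substitution import (
    OFF_DIAGONAL,
    EdgeProcess,
    ValidationError,
    calibrate,
    ens,
    gtr_rate_matrix,
    solve_ens_duration,
    transition_matrix,
    validate_distribution,
)
from .triad import TriadTree, validate_pattern_counts

GTR = "GTR"
GTR_GAMMA = "GTR+Gamma"
GENERAL = "General"
FAMILIES = (GTR, GTR_GAMMA, GENERAL)

_LOG_RATE_BOUNDS = (np.log(1e-6), np.log(200.0))  # relative exchangeabilities
_LOG_TIME_BOUNDS = (np.log(1e-8), np.log(50.0))
_LOG_SHAPE_BOUNDS = (np.log(1e-2), np.log(200.0))
_LOG_A_BOUNDS = (np.log(1e-9), np.log(100.0))  # entries of the product Q*t
_W_BOUNDS = (-30.0, 30.0)  # root softmax weights

SHAPE_MAX = 200.0

_ROWS = np.array([i for i, _ in OFF_DIAGONAL])
_COLS = np.array([j for _, j in OFF_DIAGONAL])


class FitError(RuntimeError):
    """Model fitting failed (nonconvergence or a degenerate likelihood)."""


def discrete_gamma_rates(shape: float, n_bins: int = 4) -> np.ndarray:
    """Bin-mean rates of the discretized mean-one Gamma distribution.

    The Gamma(shape, 1/shape) distribution is cut into ``n_bins`` equal
    probability bins; each bin is represented by its conditional mean, so
    the rates average exactly one.
    """
    if not shape > 0:
        raise ValidationError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, n_bins + 1), a=shape, scale=1.0 / shape)
    cum = gammainc(shape + 1.0, shape * edges[1:-1])
    cum = np.concatenate([[0.0], cum, [1.0]])
    return n_bins * np.diff(cum)


@dataclass
class FittedTriadModel:
    """A fitted (or specified) substitution model on a three-edge star."""

    family: str
    tree: TriadTree
    root_distribution: np.ndarray
    edges: dict[str, EdgeProcess]
    gamma_shape: float | None = None
    n_rate_bins: int = 4
    log_likelihood: float = np.nan
    dof: int = 0
    clock: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown model family {self.family!r}")
        self.root_distribution = validate_distribution(self.root_distribution)
        missing = [n for n in self.tree.leaf_order if n not in self.edges]
        if missing:
            raise ValidationError(f"edges missing for taxa {missing}")

    @property
    def name(self) -> str:
        return self.family + ("-clock" if self.clock else "")

    def rate_bin_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the across-site rate mixture."""
        if self.gamma_shape is None:
            return np.array([1.0]), np.array([1.0])
        rates = discrete_gamma_rates(self.gamma_shape, self.n_rate_bins)
        return rates, np.full(self.n_rate_bins, 1.0 / self.n_rate_bins)

    def pattern_probabilities(self) -> np.ndarray:
        """Model probabilities of the 64 site patterns, shape ``(4, 4, 4)``.

        ``p(x) = sum_r f(r) prod_e P_e[r, x_e]`` on the merged-root star,
        averaged over the discrete rate bins for Gamma families.
        """
        order = self.tree.leaf_order
        rates, weights = self.rate_bin_weights()
        p = np.zeros((4, 4, 4))
        for rate, wt in zip(rates, weights):
            Ps = [self.edges[n].transition_matrix(rate) for n in order]
            p += wt * np.einsum("r,ra,rb,rc->abc", self.root_distribution, *Ps)
        return p

    def edge_ens(self, leaf: str) -> float:
        """ENS length of the edge from the root to ``leaf``.

        For rate-heterogeneous families this is the iterated expectation
        over the fixed rate multipliers.
        """
        edge = self.edges[leaf]
        rates, weights = self.rate_bin_weights()
        return float(
            sum(
                wt * ens(self.root_distribution, edge.rate_matrix, edge.duration * rate)
                for rate, wt in zip(rates, weights)
            )
        )

    def ingroup_ens(self) -> tuple[float, float]:
        a, b = self.tree.ingroup
        return self.edge_ens(a), self.edge_ens(b)


def log_likelihood(model: FittedTriadModel, counts) -> float:
    """Multinomial log-likelihood of pattern counts under the model.

    Returns ``-inf`` (an explicit failure state) when a pattern with
    positive count has model probability zero; this cannot happen at an
    interior optimum with strictly positive rates.
    """
    counts = validate_pattern_counts(counts)
    p = model.pattern_probabilities()
    support = counts > 0
    if np.any(p[support] <= 0.0):
        return -np.inf
    return float(np.sum(counts[support] * np.log(p[support])))


# ---------------------------------------------------------------------------
# parameter encodings


def _softmax4(w3: np.ndarray) -> np.ndarray:
    w = np.concatenate([[0.0], w3])
    e = np.exp(w - w.max())
    return e / e.sum()


def _inv_softmax4(p: np.ndarray) -> np.ndarray:
    logp = np.log(np.clip(p, 1e-12, None))
    return (logp - logp[0])[1:]


def _gtr_decode(theta, clock, gamma):
    rates = np.append(np.exp(theta[:5]), 1.0)
    pi = _softmax4(theta[5:8])
    if clock:
        t_in, t_out = np.exp(theta[8:10])
        ts = np.array([t_in, t_in, t_out])
        k = 10
    else:
        ts = np.exp(theta[8:11])
        k = 11
    shape = np.exp(theta[k]) if gamma else None
    Q = calibrate(gtr_rate_matrix(rates, pi), pi)
    return Q, pi, ts, shape


def _gtr_encode(model: FittedTriadModel, clock: bool, gamma: bool, shape_init: float):
    order = model.tree.leaf_order
    Q = model.edges[order[0]].rate_matrix
    pi = model.root_distribution
    R = Q[_ROWS, _COLS] / np.clip(pi[_COLS], 1e-12, None)
    # upper-triangular exchangeabilities AC, AG, AT, CG, CT, GT
    iu, ju = np.triu_indices(4, 1)
    Rmat = np.zeros((4, 4))
    Rmat[_ROWS, _COLS] = R
    r6 = np.clip(Rmat[iu, ju], 1e-6, None)
    r6 = r6 / r6[5]
    ts = np.array([model.edges[n].duration for n in order])
    ts = np.clip(ts, 1e-6, None)
    theta = [np.log(r6[:5]), _inv_softmax4(pi)]
    if clock:
        theta.append(np.log([np.sqrt(ts[0] * ts[1]), ts[2]]))
    else:
        theta.append(np.log(ts))
    if gamma:
        shape = model.gamma_shape if model.gamma_shape is not None else shape_init
        theta.append(np.log([shape]))
    return np.concatenate(theta)


def _gtr_bounds(clock, gamma):
    bounds = [_LOG_RATE_BOUNDS] * 5 + [_W_BOUNDS] * 3
    bounds += [_LOG_TIME_BOUNDS] * (2 if clock else 3)
    if gamma:
        bounds.append(_LOG_SHAPE_BOUNDS)
    return bounds


def _general_decode(theta, clock):
    root = _softmax4(theta[:3])
    As = []
    for e in range(3):
        off = np.exp(theta[3 + 12 * e : 15 + 12 * e])
        A = np.zeros((4, 4))
        A[_ROWS, _COLS] = off
        np.fill_diagonal(A, -A.sum(axis=1))
        As.append(A)
    if clock:
        # ingroup edge 2 carries only a direction; its scale is solved so
        # that its ENS matches ingroup edge 1 (ENS is monotone in scale)
        target = ens(root, As[0], 1.0)
        s = solve_ens_duration(root, As[1], target, xtol=1e-12)
        As[1] = s * As[1]
    return root, As


def _general_encode(model: FittedTriadModel) -> np.ndarray:
    order = model.tree.leaf_order
    theta = [_inv_softmax4(model.root_distribution)]
    for n in order:
        A = model.edges[n].scaled
        off = np.clip(A[_ROWS, _COLS], 1e-6, None)
        theta.append(np.log(off))
    return np.concatenate(theta)


def _general_from_stationary(model: FittedTriadModel) -> np.ndarray:
    """Seed General parameters from a GTR-family fit: ``A_e = Q t_e``."""
    order = model.tree.leaf_order
    theta = [_inv_softmax4(model.root_distribution)]
    for n in order:
        edge = model.edges[n]
        A = edge.rate_matrix * max(edge.duration, 1e-6)
        theta.append(np.log(np.clip(A[_ROWS, _COLS], 1e-6, None)))
    return np.concatenate(theta)


# ---------------------------------------------------------------------------
# objectives


def _star_pattern_probs(root, Ps):
    return np.einsum("r,ra,rb,rc->abc", root, *Ps)


def _safe_loglik(counts, p, support):
    ps = np.clip(p[support], 1e-300, None)
    return float(np.sum(counts[support] * np.log(ps)))


def _gtr_objective(theta, counts, support, clock, gamma, n_bins, N):
    Q, pi, ts, shape = _gtr_decode(theta, clock, gamma)
    if gamma:
        rates = discrete_gamma_rates(shape, n_bins)
        p = np.zeros((4, 4, 4))
        for rate in rates:
            Ps = [transition_matrix(Q, t * rate) for t in ts]
            p += _star_pattern_probs(pi, Ps) / n_bins
    else:
        Ps = [transition_matrix(Q, t) for t in ts]
        p = _star_pattern_probs(pi, Ps)
    return -_safe_loglik(counts, p, support) / N


def _general_value_grad(theta, counts, support, N):
    """Negative mean log-likelihood and its analytic gradient (free fit).

    The gradient with respect to each edge's scaled generator is obtained
    in one pass from the adjoint identity for the Frechet derivative of
    the matrix exponential, ``<G, L(A, E)> = <L(A', G), E>`` with ``A'``
    the transpose.
    """
    root, As = _general_decode(theta, clock=False)
    Ps = [np.clip(expm_mat, 0.0, None) for expm_mat in (transition_matrix(A, 1.0) for A in As)]
    p = _star_pattern_probs(root, Ps)
    lnL = _safe_loglik(counts, p, support)
    W = np.where(support, counts / np.clip(p, 1e-300, None), 0.0)

    Pa, Pb, Pc = Ps
    G_root = np.einsum("abc,ra,rb,rc->r", W, Pa, Pb, Pc)
    grad_w = (root * (G_root - root @ G_root))[1:]

    G_Ps = [
        root[:, None] * np.einsum("abc,rb,rc->ra", W, Pb, Pc),
        root[:, None] * np.einsum("abc,ra,rc->rb", W, Pa, Pc),
        root[:, None] * np.einsum("abc,ra,rb->rc", W, Pa, Pb),
    ]
    grad_A_parts = []
    for A, G_P in zip(As, G_Ps):
        L = expm_frechet(A.T, G_P, compute_expm=False)
        # off-diagonal A_ij moves the diagonal A_ii in lockstep (rows sum
        # to zero), and the parameter is log A_ij
        g_off = (L[_ROWS, _COLS] - L[_ROWS, _ROWS]) * A[_ROWS, _COLS]
        grad_A_parts.append(g_off)
    grad = np.concatenate([grad_w, *grad_A_parts])
    return -lnL / N, -grad / N


def _augmented5(A):
    C = np.zeros((5, 5))
    C[:4, :4] = A
    C[:4, 4] = -np.diag(A)
    return C


def _offdiag_sensitivity(W):
    """Map a 5x5 adjoint ``W`` of the augmented matrix to off-diagonal
    sensitivities of the underlying generator.

    A change of off-diagonal ``A_ij`` moves ``C_ij`` by +1, ``C_ii`` by -1
    (zero row sums) and ``C_i5`` by +1 (the ``-diag`` column).
    """
    return W[_ROWS, _COLS] - W[_ROWS, _ROWS] + W[_ROWS, 4]


def _general_clock_value_grad(theta, counts, support, N):
    """Clock-constrained objective with an analytic gradient.

    The second ingroup edge is ``A_b = s D`` with the scale ``s`` defined
    implicitly by ``ens(root, s D) = ens(root, A_a)``; the gradient chains
    through ``s`` by implicit differentiation of that constraint.  All
    matrix-exponential sensitivities come from the adjoint Frechet
    derivative; the augmented 5x5 exponentials provide both the transition
    matrices and the ENS values of the constrained edges.
    """
    root = _softmax4(theta[:3])
    As_raw = []
    for e in range(3):
        off = np.exp(theta[3 + 12 * e : 15 + 12 * e])
        A = np.zeros((4, 4))
        A[_ROWS, _COLS] = off
        np.fill_diagonal(A, -A.sum(axis=1))
        As_raw.append(A)
    A_a, D, A_c = As_raw
    u = np.concatenate([root, [0.0]])

    Ca = _augmented5(A_a)
    Ea = expm(Ca)
    target = float(root @ Ea[:4, 4])
    s = solve_ens_duration(root, D, target, xtol=1e-12)
    Cb = _augmented5(D)
    Eb = expm(s * Cb)
    A_b = s * D

    Pa = np.clip(Ea[:4, :4], 0.0, None)
    Pb = np.clip(Eb[:4, :4], 0.0, None)
    Pc = transition_matrix(A_c, 1.0)
    p = _star_pattern_probs(root, [Pa, Pb, Pc])
    lnL = _safe_loglik(counts, p, support)
    W = np.where(support, counts / np.clip(p, 1e-300, None), 0.0)

    G_root = np.einsum("abc,ra,rb,rc->r", W, Pa, Pb, Pc)
    G_Pa = root[:, None] * np.einsum("abc,rb,rc->ra", W, Pb, Pc)
    G_Pb = root[:, None] * np.einsum("abc,ra,rc->rb", W, Pa, Pc)
    G_Pc = root[:, None] * np.einsum("abc,ra,rb->rc", W, Pa, Pb)
    G_Aa = expm_frechet(A_a.T, G_Pa, compute_expm=False)
    G_Ab = expm_frechet(A_b.T, G_Pb, compute_expm=False)
    G_Ac = expm_frechet(A_c.T, G_Pc, compute_expm=False)

    # implicit differentiation of ens(root, sD) = ens(root, A_a)
    uv = np.outer(u, np.eye(5)[4])
    W_T = expm_frechet(Ca.T, uv, compute_expm=False)  # dT/dC_a adjoint
    W_m = expm_frechet(s * Cb.T, uv, compute_expm=False)  # dm/d(sC_b) adjoint
    dT_droot = Ea[:4, 4]
    dm_droot = Eb[:4, 4]
    dT_dAa = _offdiag_sensitivity(W_T)
    dm_dD = s * _offdiag_sensitivity(W_m)
    r_b = float(root @ (Cb @ Eb)[:4, 4])  # dm/ds > 0 (ENS monotone in s)
    phi = float(np.sum(G_Ab * D))  # dlnL/ds at fixed direction

    coef = phi / r_b
    G_root_total = G_root + coef * (dT_droot - dm_droot)
    grad_w = (root * (G_root_total - root @ G_root_total))[1:]
    g_a = (G_Aa[_ROWS, _COLS] - G_Aa[_ROWS, _ROWS] + coef * dT_dAa) * A_a[_ROWS, _COLS]
    g_b = (s * (G_Ab[_ROWS, _COLS] - G_Ab[_ROWS, _ROWS]) - coef * dm_dD) * D[_ROWS, _COLS]
    g_c = (G_Ac[_ROWS, _COLS] - G_Ac[_ROWS, _ROWS]) * A_c[_ROWS, _COLS]
    grad = np.concatenate([grad_w, g_a, g_b, g_c])
    return -lnL / N, -grad / N


# ---------------------------------------------------------------------------
# optimization driver


_LBFGSB_OPTIONS = {
    "maxiter": 5000,
    "maxfun": 500_000,
    "ftol": 1e-14,
    "gtol": 1e-9,
    "maxcor": 50,
}


def _optimize(fun, starts, bounds, jac=None, args=()):
    """L-BFGS-B from every start; return the best terminal point.

    L-BFGS-B only ever accepts decreases of the objective, so the returned
    value is no worse than the best starting value — this is what makes
    seeded nested fits monotone in log-likelihood by construction.
    """
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            fun,
            x0,
            args=args,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options=_LBFGSB_OPTIONS,
        )
        f0 = fun(x0, *args)
        if jac is True:
            f0 = f0[0]
        fstar, xstar = (res.fun, res.x) if res.fun <= f0 else (f0, x0)
        if best is None or fstar < best[0]:
            best = (fstar, xstar, res)
    if not np.isfinite(best[0]):
        raise FitError(f"optimizer failed to reach a finite likelihood: {best[2].message}")
    return best[1]


def _perturbed(theta, bounds, rng, scale=0.5):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(theta + rng.normal(0.0, scale, size=theta.size), lo, hi)


def _empirical_gtr_start(counts, tree, clock):
    """Heuristic start: pooled composition and JC-corrected pairwise times."""
    counts = np.asarray(counts, dtype=float)
    N = counts.sum()
    margs = [counts.sum(axis=(1, 2)), counts.sum(axis=(0, 2)), counts.sum(axis=(0, 1))]
    pi = np.clip(sum(margs) / (3.0 * N), 1e-4, None)
    pi = pi / pi.sum()

    def jc_dist(pair_counts):
        mismatch = 1.0 - np.trace(pair_counts) / N
        mismatch = min(mismatch, 0.70)
        return max(-0.75 * np.log1p(-4.0 * mismatch / 3.0), 1e-3)

    d_ab = jc_dist(counts.sum(axis=2))
    d_ac = jc_dist(counts.sum(axis=1))
    d_bc = jc_dist(counts.sum(axis=0))
    t_a = max((d_ab + d_ac - d_bc) / 2.0, 1e-3)
    t_b = max((d_ab + d_bc - d_ac) / 2.0, 1e-3)
    t_c = max((d_ac + d_bc - d_ab) / 2.0, 1e-3)
    theta = [np.zeros(5), _inv_softmax4(pi)]
    if clock:
        theta.append(np.log([np.sqrt(t_a * t_b), t_c]))
    else:
        theta.append(np.log([t_a, t_b, t_c]))
    return np.concatenate(theta)


def _resolve_inits(init) -> list[FittedTriadModel]:
    if init is None:
        return []
    if isinstance(init, FittedTriadModel):
        return [init]
    return list(init)


# ---------------------------------------------------------------------------
# public fit functions


def fit_gtr(
    counts,
    tree: TriadTree,
    *,
    clock: bool = False,
    init=None,
    n_restarts: int = 0,
    seed: int | None = None,
) -> FittedTriadModel:
    """ML fit of the GTR model (shared calibrated reversible generator).

    ``init`` may be a fitted model (or list of models) used as starting
    point(s) in addition to restarts; an empirical heuristic start is used
    otherwise.  With ``clock=True`` the ingroup durations share a single
    parameter, so their ENS lengths are equal exactly.
    """
    counts = validate_pattern_counts(counts)
    if counts.sum() == 0:
        raise FitError("cannot fit to an empty alignment")
    support = counts > 0
    N = float(counts.sum())
    bounds = _gtr_bounds(clock, gamma=False)
    starts = [_gtr_encode(m, clock, False, 5.0) for m in _resolve_inits(init)]
    if not starts:
        starts = [_empirical_gtr_start(counts, tree, clock)]
    rng = np.random.default_rng(seed)
    starts += [_perturbed(starts[0], bounds, rng) for _ in range(n_restarts)]
    theta = _optimize(
        _gtr_objective, starts, bounds, args=(counts, support, clock, False, 4, N)
    )
    return _build_gtr_model(theta, counts, tree, clock, gamma=False)


def fit_gtr_gamma(
    counts,
    tree: TriadTree,
    *,
    init=None,
    clock: bool = False,
    n_restarts: int = 0,
    seed: int | None = None,
    fixed_shape: float | None = None,
    shape_init: float = 5.0,
    n_bins: int = 4,
) -> FittedTriadModel:
    """ML fit of GTR with discrete-Gamma rate heterogeneity (four bins).

    Normally seeded from a GTR fit on the same counts (``init``).  With
    ``fixed_shape`` the shape parameter is pinned (used, e.g., to probe the
    large-shape limit where the model collapses onto GTR).
    """
    counts = validate_pattern_counts(counts)
    support = counts > 0
    N = float(counts.sum())
    if fixed_shape is not None:

        def objective(theta, *args):
            full = np.concatenate([theta, [np.log(fixed_shape)]])
            return _gtr_objective(full, *args)

        bounds = _gtr_bounds(clock, gamma=False)
        starts = [_gtr_encode(m, clock, False, shape_init) for m in _resolve_inits(init)]
        if not starts:
            starts = [_empirical_gtr_start(counts, tree, clock)]
        rng = np.random.default_rng(seed)
        starts += [_perturbed(starts[0], bounds, rng) for _ in range(n_restarts)]
        theta = _optimize(objective, starts, bounds, args=(counts, support, clock, True, n_bins, N))
        theta = np.concatenate([theta, [np.log(fixed_shape)]])
    else:
        bounds = _gtr_bounds(clock, gamma=True)
        starts = [_gtr_encode(m, clock, True, shape_init) for m in _resolve_inits(init)]
        if not starts:
            starts = [
                np.concatenate([_empirical_gtr_start(counts, tree, clock), [np.log(shape_init)]])
            ]
        rng = np.random.default_rng(seed)
        starts += [_perturbed(starts[0], bounds, rng) for _ in range(n_restarts)]
        theta = _optimize(
            _gtr_objective, starts, bounds, args=(counts, support, clock, True, n_bins, N)
        )
    return _build_gtr_model(theta, counts, tree, clock, gamma=True, n_bins=n_bins)


def _build_gtr_model(theta, counts, tree, clock, gamma, n_bins=4):
    Q, pi, ts, shape = _gtr_decode(theta, clock, gamma)
    order = tree.leaf_order
    edges = {n: EdgeProcess(Q, float(t)) for n, t in zip(order, ts)}
    dof = (11 if not gamma else 12) - (1 if clock else 0)
    model = FittedTriadModel(
        family=GTR_GAMMA if gamma else GTR,
        tree=tree,
        root_distribution=pi,
        edges=edges,
        gamma_shape=shape,
        n_rate_bins=n_bins,
        dof=dof,
        clock=clock,
    )
    model.log_likelihood = log_likelihood(model, counts)
    if not np.isfinite(model.log_likelihood):
        raise FitError("fit terminated at a zero-probability pattern")
    return model


def fit_general(
    counts,
    tree: TriadTree,
    *,
    init=None,
    clock: bool = False,
    n_restarts: int = 0,
    seed: int | None = None,
) -> FittedTriadModel:
    """ML fit of the General model (free generator per edge, free root).

    The identifiable per-edge products ``A = Q t`` are optimized directly.
    ``init`` is normally the GTR fit on the same counts; if omitted a GTR
    fit is performed first.  The clock variant parameterizes the second
    ingroup edge by a direction whose scale is solved from the constraint
    that both ingroup ENS lengths agree.
    """
    counts = validate_pattern_counts(counts)
    if counts.sum() == 0:
        raise FitError("cannot fit to an empty alignment")
    support = counts > 0
    N = float(counts.sum())
    inits = _resolve_inits(init)
    if not inits:
        inits = [fit_gtr(counts, tree, clock=clock)]
    starts = []
    for m in inits:
        if m.family == GENERAL:
            starts.append(_general_encode(m))
        else:
            starts.append(_general_from_stationary(m))
    bounds = [_W_BOUNDS] * 3 + [_LOG_A_BOUNDS] * 36
    rng = np.random.default_rng(seed)
    starts += [_perturbed(starts[0], bounds, rng) for _ in range(n_restarts)]
    objective = _general_clock_value_grad if clock else _general_value_grad
    theta = _optimize(objective, starts, bounds, jac=True, args=(counts, support, N))
    root, As = _general_decode(theta, clock)
    edges = {n: EdgeProcess(A, 1.0) for n, A in zip(tree.leaf_order, As)}
    model = FittedTriadModel(
        family=GENERAL,
        tree=tree,
        root_distribution=root,
        edges=edges,
        dof=39 - (1 if clock else 0),
        clock=clock,
    )
    model.log_likelihood = log_likelihood(model, counts)
    if not np.isfinite(model.log_likelihood):
        raise FitError("fit terminated at a zero-probability pattern")
    return model


def sequential_fit(
    counts,
    tree: TriadTree,
    *,
    families=(GTR, GTR_GAMMA, GENERAL),
    clock_suite: bool = False,
    n_restarts: int = 0,
    seed: int | None = None,
) -> dict[str, FittedTriadModel]:
    """Fit nested models in order of increasing generality, with seeding.

    Richer models start from the simpler model's optimum, so within each
    nested chain the log-likelihood is nondecreasing.  With
    ``clock_suite=True`` each family is fitted in both clock-constrained
    and free form (the free fit is additionally seeded from the clock fit,
    guaranteeing ``lnL(free) >= lnL(clock)``), for consumption by the
    likelihood-ratio clock test.
    """
    counts = validate_pattern_counts(counts)
    fits: dict[str, FittedTriadModel] = {}
    kw = {"n_restarts": n_restarts, "seed": seed}

    gtr_clock = fit_gtr(counts, tree, clock=True, **kw) if clock_suite else None
    if gtr_clock is not None:
        fits["GTR-clock"] = gtr_clock
    gtr_free = fit_gtr(counts, tree, init=gtr_clock, **kw)
    fits[GTR] = gtr_free

    if GTR_GAMMA in families:
        if clock_suite:
            fits["GTR+Gamma-clock"] = fit_gtr_gamma(counts, tree, init=gtr_clock, clock=True, **kw)
            fits[GTR_GAMMA] = fit_gtr_gamma(
                counts, tree, init=[gtr_free, fits["GTR+Gamma-clock"]], **kw
            )
        else:
            fits[GTR_GAMMA] = fit_gtr_gamma(counts, tree, init=gtr_free, **kw)

    if GENERAL in families:
        if clock_suite:
            fits["General-clock"] = fit_general(counts, tree, init=gtr_clock, clock=True, **kw)
            fits[GENERAL] = fit_general(
                counts, tree, init=[gtr_free, fits["General-clock"]], **kw
            )
        else:
            fits[GENERAL] = fit_general(counts, tree, init=gtr_free, **kw)
    return fits
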