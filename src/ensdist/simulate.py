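"""Synthetic triad alignments under any fitted-model-shaped process.

Sites are independent and identically distributed: a root state is drawn
from the root distribution (plus a rate bin for Gamma families) and
evolved independently along the three star edges through each edge's
transition matrix.  Only end states matter for an alignment, so states are
sampled directly from transition probabilities rather than by simulating
waiting times.

Randomness is organized as one stream for the root states, one for the
rate bins, and one per edge, all spawned from the master seed, so draws on
one edge do not perturb the others.
"""

from __future__ import annotations

import numpy as np

from .fitting import GENERAL, FittedTriadModel
from .substitution import (
    NUCLEOTIDES,
    EdgeProcess,
    ValidationError,
    calibrate,
    make_rate_matrix,
    solve_ens_duration,
    stationary_distribution,
)
from .triad import TriadAlignment, TriadTree

from .distances import jsd  # noqa: E402  (leaf-level import to avoid cycles)


def _draw_states(rng, cum_rows, parents):
    u = rng.random(parents.size)
    return (u[:, None] > cum_rows[parents]).sum(axis=1)


def simulate_alignment(model: FittedTriadModel, n_sites: int, seed) -> TriadAlignment:
    """Simulate a triad alignment of ``n_sites`` i.i.d. columns.

    Reproducible: a fixed ``seed`` yields a byte-identical alignment.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be a positive integer")
    order = model.tree.leaf_order
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    root_rng, bin_rng, *edge_rngs = (np.random.default_rng(s) for s in ss.spawn(2 + len(order)))

    root_cum = np.cumsum(model.root_distribution)
    u = root_rng.random(n_sites)
    root_states = (u[:, None] > root_cum[None, :]).sum(axis=1)

    rates, weights = model.rate_bin_weights()
    if len(rates) > 1:
        bin_cum = np.cumsum(weights)
        ub = bin_rng.random(n_sites)
        bins = (ub[:, None] > bin_cum[None, :]).sum(axis=1)
    else:
        bins = np.zeros(n_sites, dtype=int)

    base = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    seqs = {}
    for name, rng in zip(order, edge_rngs):
        cum_by_bin = [
            np.cumsum(np.clip(model.edges[name].transition_matrix(r), 0.0, None), axis=1)
            for r in rates
        ]
        states = np.empty(n_sites, dtype=int)
        u = rng.random(n_sites)
        for b, cum in enumerate(cum_by_bin):
            mask = bins == b
            if mask.any():
                states[mask] = (u[mask, None] > cum[root_states[mask]]).sum(axis=1)
        seqs[name] = base[states].tobytes().decode()
    return TriadAlignment(seqs)


def random_general_model(
    seed,
    tree: TriadTree | None = None,
    ens_range: tuple[float, float] = (0.05, 0.5),
    jsd_floor: float = 0.0,
    clock: bool = False,
    rate_spread: float = 1.0,
    root_concentration: float = 1.5,
    max_attempts: int = 1000,
) -> FittedTriadModel:
    """Random General-model parameter set with controlled nonstationarity.

    Per edge, a random direction with lognormal off-diagonal rates is
    rescaled so its ENS falls uniformly in ``ens_range``; the root
    distribution is Dirichlet.  With ``jsd_floor > 0`` parameter sets are
    rejection-sampled until the Jensen-Shannon divergence between the root
    distribution and every leaf marginal reaches the floor, emulating
    measurably nonstationary data.  ``clock=True`` rescales the second
    ingroup edge so both ingroup ENS lengths coincide.
    """
    if tree is None:
        tree = TriadTree(("a", "b"), "c")
    lo, hi = ens_range
    if not (0 <= lo <= hi):
        raise ValidationError("invalid ens_range")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        root = rng.dirichlet(np.full(4, root_concentration))
        root = np.clip(root, 1e-3, None)
        root = root / root.sum()
        edges = {}
        targets = rng.uniform(lo, hi, size=3)
        if clock:
            targets[1] = targets[0]
        ok = True
        for name, target in zip(tree.leaf_order, targets):
            D = make_rate_matrix(np.exp(rng.normal(0.0, rate_spread, size=12)))
            s = solve_ens_duration(root, D, target)
            A = s * D
            edges[name] = EdgeProcess(A, 1.0)
            marginal = root @ edges[name].transition_matrix()
            if jsd_floor > 0 and jsd([root, marginal]) < jsd_floor:
                ok = False
                break
        if ok:
            return FittedTriadModel(
                family=GENERAL,
                tree=tree,
                root_distribution=root,
                edges=edges,
                dof=39 - (1 if clock else 0),
                clock=clock,
            )
    raise ValidationError(
        f"could not satisfy jsd_floor={jsd_floor} within {max_attempts} attempts"
    )


def stationary_triad_model(
    Q,
    durations: tuple[float, float, float],
    tree: TriadTree | None = None,
    gamma_shape: float | None = None,
) -> FittedTriadModel:
    """A GTR-shaped model from a reversible generator and edge durations.

    The generator is calibrated and the root distribution set to its
    stationary distribution, so edge durations are ENS lengths.
    """
    if tree is None:
        tree = TriadTree(("a", "b"), "c")
    Qc = calibrate(Q)
    pi = stationary_distribution(Qc)
    edges = {n: EdgeProcess(Qc, float(t)) for n, t in zip(tree.leaf_order, durations)}
    from .fitting import GTR, GTR_GAMMA

    return FittedTriadModel(
        family=GTR_GAMMA if gamma_shape is not None else GTR,
        tree=tree,
        root_distribution=pi,
        edges=edges,
        gamma_shape=gamma_shape,
        dof=12 if gamma_shape is not None else 11,
    )


def rate_multiplied(model: FittedTriadModel, leaf: str, k: float) -> FittedTriadModel:
    """Multiply the substitution rates on one edge by ``k`` (same duration).

    Used to simulate clock violations: with generator ``Q`` on one ingroup
    edge and ``kQ`` on the other, the ENS lengths differ roughly by the
    factor ``k`` (exactly ``k`` for a stationary root).
    """
    if k <= 0:
        raise ValidationError("rate multiplier must be positive")
    edges = dict(model.edges)
    old = edges[leaf]
    edges[leaf] = EdgeProcess(old.rate_matrix * k, old.duration)
    out = FittedTriadModel(
        family=model.family,
        tree=model.tree,
        root_distribution=model.root_distribution,
        edges=edges,
        gamma_shape=model.gamma_shape,
        n_rate_bins=model.n_rate_bins,
        dof=model.dof,
        clock=False,
    )
    return out
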