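"""Goodness of fit, identifiability filters, and molecular-clock testing.

Goodness of fit compares fitted site-pattern expectations against observed
counts with the G statistic; its null distribution is obtained by
parametric bootstrap (simulate under the fitted model, refit, recompute
G).  Two identifiability filters flag fits whose transition matrices do
not pin down the underlying continuous-time process: the
diagonal-largest-in-column (DLC) condition (internal-state labeling) and
a conservative spectral criterion for uniqueness of the real matrix
logarithm (one generator per transition matrix).  The molecular clock is
tested by a one-degree-of-freedom likelihood-ratio test between a
clock-constrained fit and its free counterpart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .fitting import (
    GENERAL,
    GTR,
    GTR_GAMMA,
    FitError,
    FittedTriadModel,
    fit_general,
    fit_gtr,
    fit_gtr_gamma,
)
from .substitution import ValidationError, validate_transition_matrix
from .triad import pattern_counts, validate_pattern_counts

logger = logging.getLogger(__name__)

_DLC_TOL = 1e-12


def expected_counts(model: FittedTriadModel, n_sites: float) -> np.ndarray:
    """Expected site-pattern counts: model probabilities times length."""
    return model.pattern_probabilities() * float(n_sites)


def g_statistic(observed, expected) -> float:
    """The G goodness-of-fit statistic ``2 sum O ln(O/E)``.

    Summed over patterns with positive observed count (``0 ln 0 = 0``);
    equals the likelihood-ratio statistic of the fitted model against the
    saturated multinomial on the 64 patterns.  Returns ``inf`` when a
    pattern was observed but has zero expectation.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if observed.shape != expected.shape:
        raise ValidationError("observed and expected shapes differ")
    if abs(observed.sum() - expected.sum()) > 1e-6 * max(observed.sum(), 1.0):
        raise ValidationError("observed and expected totals disagree")
    support = observed > 0
    if np.any(expected[support] <= 0.0):
        return float("inf")
    return float(2.0 * np.sum(observed[support] * np.log(observed[support] / expected[support])))


def _refit_family(model: FittedTriadModel, counts):
    """Refit the family of ``model`` to new counts.

    Replicate fits repeat the original fitting procedure (sequential
    seeding from the simpler model, heuristic start) rather than starting
    from the null parameters: starting replicates at their own generating
    values, but the observed fit at a heuristic, converges the replicates
    systematically better and deflates the bootstrap P-value.
    """
    if model.family == GTR:
        return fit_gtr(counts, model.tree, clock=model.clock)
    if model.family == GTR_GAMMA:
        seed_fit = fit_gtr(counts, model.tree, clock=model.clock)
        return fit_gtr_gamma(counts, model.tree, clock=model.clock, init=seed_fit)
    if model.family == GENERAL:
        return fit_general(counts, model.tree, clock=model.clock)
    raise ValidationError(f"unknown family {model.family!r}")


@dataclass
class BootstrapResult:
    p_value: float
    g_observed: float
    g_replicates: list[float] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def rejected(self) -> bool:
        """Convenience predicate: fit rejected at the 5% level."""
        return self.p_value < 0.05


def parametric_bootstrap_pvalue(
    fit: FittedTriadModel,
    observed_counts,
    n_reps: int = 100,
    seed: int | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap P-value for the G goodness-of-fit statistic.

    Simulates ``n_reps`` alignments of the original length under the
    fitted model (the null hypothesis), refits the same family to each,
    and reports the proportion of replicate G statistics exceeding the
    observed one.  With the default 100 replicates the P-value has
    resolution 0.01.  Replicates whose refit fails are excluded and
    counted in ``n_excluded``.
    """
    from .simulate import simulate_alignment

    observed_counts = validate_pattern_counts(observed_counts)
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    n_sites = int(observed_counts.sum())
    g_obs = g_statistic(observed_counts, expected_counts(fit, n_sites))
    ss = np.random.SeedSequence(seed)
    g_reps: list[float] = []
    n_excluded = 0
    for rep_seed in ss.spawn(n_reps):
        aln = simulate_alignment(fit, n_sites, rep_seed)
        rep_counts = pattern_counts(aln, fit.tree)
        try:
            rep_fit = _refit_family(fit, rep_counts)
        except FitError:
            logger.warning("bootstrap replicate fit failed; excluding")
            n_excluded += 1
            continue
        g_reps.append(g_statistic(rep_counts, expected_counts(rep_fit, n_sites)))
    if not g_reps:
        raise FitError("all bootstrap replicate fits failed")
    p = sum(g > g_obs for g in g_reps) / len(g_reps)
    return BootstrapResult(p, g_obs, g_reps, n_excluded)


def dlc_check(P) -> bool:
    """Diagonal-largest-in-column check on a transition matrix.

    True iff ``P[j, j]`` strictly exceeds every other entry of column
    ``j``; ties (within 1e-12) fail, since DLC is a sufficient condition
    requiring strictness.  DLC guarantees that internal-node state labels
    cannot be permuted without changing the likelihood.
    """
    P = validate_transition_matrix(P)
    for j in range(4):
        col = np.delete(P[:, j], j)
        if not np.all(P[j, j] - col > _DLC_TOL):
            return False
    return True


def unique_mapping_check(P, rel_tol: float = 1e-8) -> bool:
    """Conservative check that ``P`` has a unique real generator.

    True iff all eigenvalues of ``P`` are real, strictly positive, and
    distinct — then the principal logarithm is the only real logarithm,
    so at most one rate matrix can produce ``P``.  Any other spectrum
    (including ``det P <= 0``, complex pairs, or repeated eigenvalues) is
    conservatively reported as a possibly nonunique mapping and the fit
    should be rejected.
    """
    P = validate_transition_matrix(P)
    if np.linalg.det(P) <= 0:
        return False
    lam = np.linalg.eigvals(P)
    scale = max(np.abs(lam).max(), 1.0)
    if np.any(np.abs(lam.imag) > rel_tol * scale):
        return False
    real = np.sort(lam.real)
    if real[0] <= rel_tol * scale:
        return False
    if np.any(np.diff(real) <= rel_tol * scale):
        return False
    return True


def identifiability_flags(model: FittedTriadModel) -> dict[str, dict[str, bool]]:
    """DLC and unique-mapping flags for every edge's transition matrix."""
    flags = {}
    for leaf in model.tree.leaf_order:
        P = model.edges[leaf].transition_matrix()
        flags[leaf] = {"dlc": dlc_check(P), "unique_mapping": unique_mapping_check(P)}
    return flags


def clock_lrt(clock_fit: FittedTriadModel, free_fit: FittedTriadModel) -> float:
    """Relative-rate molecular clock likelihood-ratio test P-value.

    The null (clock) model constrains the two ingroup edges to equal ENS
    length and is nested in the free model with one fewer degree of
    freedom; ``2 (lnL_free - lnL_clock)`` is referred to the chi-squared
    distribution with one degree of freedom.
    """
    if clock_fit.family != free_fit.family:
        raise ValidationError("clock and free fits must be from the same family")
    if not clock_fit.clock or free_fit.clock:
        raise ValidationError("expected a clock-constrained null and a free alternative")
    if free_fit.dof - clock_fit.dof != 1:
        raise ValidationError("clock test requires exactly one constrained parameter")
    delta = free_fit.log_likelihood - clock_fit.log_likelihood
    if delta < -1e-6:
        raise FitError(
            f"free fit has lower log-likelihood than clock fit (delta={delta:.3g}); "
            "optimizer failure"
        )
    statistic = max(2.0 * delta, 0.0)
    return float(chi2.sf(statistic, df=1))


def aic(fit: FittedTriadModel) -> float:
    """Akaike information criterion ``2 dof - 2 lnL``."""
    return float(2.0 * fit.dof - 2.0 * fit.log_likelihood)


def edge_length_ratio(fit: FittedTriadModel, leaf_a: str, leaf_b: str) -> float:
    """Ratio of two edge lengths under the fit's own distance (edge ENS)."""
    denom = fit.edge_ens(leaf_b)
    if denom <= 0:
        raise ValidationError(f"edge to {leaf_b!r} has zero ENS length")
    return float(fit.edge_ens(leaf_a) / denom)


@dataclass
class FitDiagnostics:
    """Bundle of per-fit diagnostics."""

    g_statistic: float
    aic: float
    dlc_pass: dict[str, bool]
    unique_mapping_pass: dict[str, bool]
    bootstrap_p: float | None = None
    bootstrap_excluded: int = 0

    @property
    def all_identifiable(self) -> bool:
        return all(self.dlc_pass.values()) and all(self.unique_mapping_pass.values())


def diagnose_fit(
    fit: FittedTriadModel,
    observed_counts,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> FitDiagnostics:
    """Compute the standard diagnostics for one fitted model."""
    observed_counts = validate_pattern_counts(observed_counts)
    flags = identifiability_flags(fit)
    g = g_statistic(observed_counts, expected_counts(fit, observed_counts.sum()))
    result = FitDiagnostics(
        g_statistic=g,
        aic=aic(fit),
        dlc_pass={leaf: f["dlc"] for leaf, f in flags.items()},
        unique_mapping_pass={leaf: f["unique_mapping"] for leaf, f in flags.items()},
    )
    if n_bootstrap:
        boot = parametric_bootstrap_pvalue(fit, observed_counts, n_reps=n_bootstrap, seed=seed)
        result.bootstrap_p = boot.p_value
        result.bootstrap_excluded = boot.n_excluded
    return result
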