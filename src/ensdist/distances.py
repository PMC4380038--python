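"""Distance and composition measures.

Model-based distances (the ENS path distance and its stationary
counterparts) are read off fitted triad models; the paralinear and LogDet
distances are computed directly from empirical joint distributions of
aligned sequence pairs and require no model at all.  Composition measures
(Shannon entropy, equally weighted Jensen-Shannon divergence, G+C
content) quantify departure from compositional homogeneity.
"""

from __future__ import annotations

import numpy as np

from .substitution import NT_INDEX, ValidationError, validate_distribution
from .triad import TriadAlignment


class SaturationError(ValueError):
    """A determinant-based distance is undefined (nonpositive determinant)."""


def ens_path_distance(model, a: str, b: str) -> float:
    """ENS distance between two nodes of a fitted triad: the sum of edge
    ENS lengths along the path between them.

    On the merged-root star every edge starts at the root, so each edge's
    ENS is evaluated with the fitted root distribution as its initial
    distribution.  The distance is symmetric and zero for ``a == b``.
    """
    nodes = model.tree.nodes
    for node in (a, b):
        if node not in nodes:
            raise ValidationError(f"node {node!r} not in tree (have {nodes})")
    if a == b:
        return 0.0
    path = [n for n in (a, b) if n != "root"]
    return float(sum(model.edge_ens(leaf) for leaf in path))


def empirical_joint(seq_a: str, seq_b: str) -> np.ndarray:
    """Empirical joint distribution of aligned base pairs, shape ``(4, 4)``.

    Entry ``(i, j)`` is the fraction of columns with base ``i`` in
    ``seq_a`` and base ``j`` in ``seq_b``; rows/columns marginalize to the
    two sequence compositions.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError("sequences must have equal length")
    if len(seq_a) == 0:
        raise ValidationError("sequences must be non-empty")
    table = np.full(128, -1, dtype=np.int8)
    for c, i in NT_INDEX.items():
        table[ord(c)] = i
    ia = table[np.frombuffer(seq_a.encode(), dtype=np.uint8)]
    ib = table[np.frombuffer(seq_b.encode(), dtype=np.uint8)]
    if np.any(ia < 0) or np.any(ib < 0):
        raise ValidationError("sequences must contain only A, C, G, T")
    J = np.bincount(ia * 4 + ib, minlength=16).reshape(4, 4).astype(float)
    return J / J.sum()


def _validate_joint(J) -> np.ndarray:
    J = np.asarray(J, dtype=float)
    if J.shape != (4, 4):
        raise ValidationError("joint distribution must be 4x4")
    if np.any(J < 0) or abs(J.sum() - 1.0) > 1e-9:
        raise ValidationError("joint distribution entries must be nonnegative and sum to 1")
    return J


def paralinear_distance(J, pseudocount: float = 0.0) -> float:
    """Paralinear distance from a joint distribution of aligned pairs:

        d_para = -1/4 ln det( diag(pi_u)^{-1/2} J diag(pi_v)^{-1/2} )

    with the marginals ``pi_u, pi_v`` taken from the row and column sums
    of ``J``.  Intended as a model-free approximation to the expected
    number of substitutions that remains valid under nonstationarity; it
    is zero when ``J`` is diagonal (identity transition).

    ``pseudocount`` optionally adds a small Laplace-style mass to every
    cell before normalization (off by default: raw frequencies are used).
    Raises :class:`SaturationError` when a marginal frequency is zero or
    the normalized determinant is nonpositive (saturated divergence).
    """
    J = _validate_joint(J)
    if pseudocount:
        J = J + pseudocount / J.size
        J = J / J.sum()
    pu = J.sum(axis=1)
    pv = J.sum(axis=0)
    if np.any(pu <= 0) or np.any(pv <= 0):
        raise SaturationError("a marginal base frequency is zero")
    sign, logdet = np.linalg.slogdet(J)
    if sign <= 0:
        raise SaturationError("joint distribution has nonpositive determinant")
    value = -0.25 * (logdet - 0.5 * np.sum(np.log(pu)) - 0.5 * np.sum(np.log(pv)))
    return float(value)


def paralinear_from_transition(pi_u, P) -> float:
    """Paralinear distance in its transition-matrix form,

        d_para = -1/4 ln det( diag(pi_u)^{1/2} P diag(pi_v)^{-1/2} ),

    with ``pi_v = pi_u P``.  Algebraically identical to the joint form;
    kept as an independent route for cross-checking.
    """
    pi_u = validate_distribution(pi_u)
    P = np.asarray(P, dtype=float)
    pi_v = pi_u @ P
    if np.any(pi_u <= 0) or np.any(pi_v <= 0):
        raise SaturationError("a marginal base frequency is zero")
    sign, logdet = np.linalg.slogdet(P)
    if sign <= 0:
        raise SaturationError("transition matrix has nonpositive determinant")
    value = -0.25 * (0.5 * np.sum(np.log(pi_u)) + logdet - 0.5 * np.sum(np.log(pi_v)))
    return float(value)


def logdet_distance(J) -> float:
    """The LogDet transformation ``-ln det J``.

    Unlike the paralinear distance this does not estimate edge lengths
    (it has no interpretation as an expected number of substitutions);
    provided for comparison only.
    """
    J = _validate_joint(J)
    sign, logdet = np.linalg.slogdet(J)
    if sign <= 0:
        raise SaturationError("joint distribution has nonpositive determinant")
    return float(-logdet)


def shannon_entropy(p) -> float:
    """Shannon entropy in natural-log units, with ``0 ln 0 = 0``."""
    p = validate_distribution(p)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def jsd(distributions) -> float:
    """Equally weighted Jensen-Shannon divergence among composition vectors:

        JSD = H(mean of p_i) - mean of H(p_i)

    in natural-log units.  Zero iff all distributions coincide; bounded by
    ``ln n``.  Used as the measure of departure from compositional
    homogeneity among sequences.
    """
    ps = [validate_distribution(p) for p in distributions]
    if len(ps) < 2:
        raise ValidationError("JSD requires at least two distributions")
    mixture = np.mean(ps, axis=0)
    return float(shannon_entropy(mixture) - np.mean([shannon_entropy(p) for p in ps]))


def sequence_composition(seq: str) -> np.ndarray:
    """Empirical nucleotide frequencies of a sequence."""
    if len(seq) == 0:
        raise ValidationError("sequence must be non-empty")
    counts = np.zeros(4)
    for c, i in NT_INDEX.items():
        counts[i] = seq.count(c)
    if counts.sum() != len(seq):
        raise ValidationError("sequence must contain only A, C, G, T")
    return counts / counts.sum()


def alignment_jsd(aln: TriadAlignment) -> float:
    """Equally weighted JSD of the three sequence compositions."""
    return jsd([sequence_composition(s) for s in aln.sequences.values()])


def gc_content(seq: str) -> float:
    """Fraction of G + C nucleotides in an ACGT sequence."""
    comp = sequence_composition(seq)
    return float(comp[NT_INDEX["G"]] + comp[NT_INDEX["C"]])
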