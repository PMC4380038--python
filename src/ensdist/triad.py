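"""Triad trees, alignments, and site-pattern counts.

A *triad* is a rooted three-taxon tree with a declared ingroup pair and an
outgroup.  Because the parameters of the two edges emanating from the root
are not separately identifiable, those edges are merged and the fitted
process is rooted at the internal node joining the ingroup: the fitted
topology is a three-edge star whose root is the ingroup ancestor.

All site-level information in a triad alignment is carried by the counts
of the 64 ordered site patterns (one nucleotide per taxon, taxa in
``(ingroup_1, ingroup_2, outgroup)`` order), stored as a ``(4, 4, 4)``
integer array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .substitution import NT_INDEX, NUCLEOTIDES, ValidationError


@dataclass(frozen=True)
class TriadTree:
    """Rooted three-taxon topology with merged root edges."""

    ingroup: tuple[str, str]
    outgroup: str

    def __post_init__(self):
        if len(set(self.ingroup)) != 2:
            raise ValidationError("ingroup must name two distinct taxa")
        if self.outgroup in self.ingroup:
            raise ValidationError("outgroup must be distinct from the ingroup")
        object.__setattr__(self, "ingroup", tuple(self.ingroup))

    @property
    def leaf_order(self) -> tuple[str, str, str]:
        """Fixed taxon order: ingroup pair first, then the outgroup."""
        return (*self.ingroup, self.outgroup)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (*self.leaf_order, "root")


@dataclass(frozen=True)
class TriadAlignment:
    """Three equal-length sequences over the strict ``ACGT`` alphabet."""

    sequences: dict[str, str]
    removed_columns: int = 0

    def __post_init__(self):
        if len(self.sequences) != 3:
            raise ValidationError("a triad alignment needs exactly 3 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
        for name, seq in self.sequences.items():
            bad = set(seq) - set(NUCLEOTIDES)
            if bad:
                col = min(i for i, c in enumerate(seq) if c in bad)
                raise ValidationError(
                    f"sequence {name!r} has non-ACGT character at column {col + 1}"
                )

    def __len__(self) -> int:
        return len(next(iter(self.sequences.values())))

    def encoded(self, order: tuple[str, str, str]) -> np.ndarray:
        """Integer-encode the alignment, shape ``(3, n_sites)``."""
        missing = [n for n in order if n not in self.sequences]
        if missing:
            raise ValidationError(f"alignment is missing taxa {missing}")
        table = np.full(128, -1, dtype=np.int8)
        for c, i in NT_INDEX.items():
            table[ord(c)] = i
        return np.vstack(
            [table[np.frombuffer(self.sequences[n].encode(), dtype=np.uint8)] for n in order]
        )


def pattern_counts(aln: TriadAlignment, tree: TriadTree) -> np.ndarray:
    """Counts of the 64 ordered site patterns as a ``(4, 4, 4)`` array.

    Axis order follows ``tree.leaf_order``; the counts sum to the
    alignment length.
    """
    enc = aln.encoded(tree.leaf_order)
    flat = (enc[0] * 16 + enc[1] * 4 + enc[2]).astype(np.int64)
    return np.bincount(flat, minlength=64).reshape(4, 4, 4)


def validate_pattern_counts(counts) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.shape == (64,):
        counts = counts.reshape(4, 4, 4)
    if counts.shape != (4, 4, 4):
        raise ValidationError("pattern counts must have shape (4, 4, 4) or (64,)")
    if np.any(counts < 0):
        raise ValidationError("pattern counts must be nonnegative")
    return counts


def pattern_labels() -> list[str]:
    """The 64 ordered triplet labels, e.g. ``'AAA', 'AAC', ...``."""
    return [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
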