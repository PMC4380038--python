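"""File formats, reports, and the batch analysis pipeline.

Alignments are plain FASTA; columns containing gap or IUPAC ambiguity
characters are removed on input, mirroring standard practice for distance
estimation from coding alignments.  Fitted models round-trip through a
JSON representation (used both for simulator parameter sidecars and for
report records).  Batch analyses emit one report record per alignment as
JSON-lines or TSV; records are flat, schema-versioned dictionaries so
they can be consumed directly by external regression or plotting tools.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diagnostics import aic, clock_lrt, diagnose_fit, edge_length_ratio
from .distances import (
    SaturationError,
    alignment_jsd,
    empirical_joint,
    ens_path_distance,
    gc_content,
    logdet_distance,
    paralinear_distance,
)
from .fitting import (
    GENERAL,
    GTR,
    GTR_GAMMA,
    FitError,
    FittedTriadModel,
    sequential_fit,
)
from .substitution import NUCLEOTIDES, EdgeProcess, ValidationError
from .triad import TriadAlignment, TriadTree, pattern_counts

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: minimum number of unambiguous, ungapped sites for an alignment to be used
DEFAULT_MIN_LENGTH = 500


def read_triad_fasta(
    path,
    leaf_names: tuple[str, str, str] | None = None,
    min_length: int | None = DEFAULT_MIN_LENGTH,
) -> TriadAlignment:
    """Read a triad alignment from FASTA, dropping unusable columns.

    Columns containing any character outside ``A, C, G, T`` (gaps, IUPAC
    ambiguity codes, masked bases) are removed from all sequences; the
    number removed is recorded on the returned alignment.  Alignments
    shorter than ``min_length`` after filtering are rejected (pass
    ``min_length=None`` or 0 to disable).
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if leaf_names is None:
        if len(records) != 3:
            raise ValidationError(
                f"{path}: expected exactly 3 sequences when leaf_names is not "
                f"given, found {len(records)}"
            )
        leaf_names = tuple(records)
    missing = [n for n in leaf_names if n not in records]
    if missing:
        raise ValidationError(f"{path}: missing taxa {missing}")
    seqs = [records[n] for n in leaf_names]
    if len({len(s) for s in seqs}) != 1:
        raise ValidationError(f"{path}: sequences have unequal lengths (malformed alignment)")
    arr = np.array([list(s) for s in seqs])
    good = np.all(np.isin(arr, list(NUCLEOTIDES)), axis=0)
    n_removed = int((~good).sum())
    if n_removed:
        logger.info("%s: removed %d gap/ambiguity columns", path, n_removed)
    filtered = ["".join(row) for row in arr[:, good]]
    if min_length and len(filtered[0]) < min_length:
        raise ValidationError(
            f"{path}: only {len(filtered[0])} unambiguous sites after filtering "
            f"(minimum {min_length})"
        )
    return TriadAlignment(dict(zip(leaf_names, filtered)), removed_columns=n_removed)


def write_triad_fasta(aln: TriadAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def tree_from_newick(source: str) -> TriadTree:
    """Triad topology from a rooted three-taxon newick string.

    The cherry (the pair under the internal node) is the ingroup and the
    remaining taxon the outgroup, e.g. ``((human,mouse),opossum);``.
    """
    import dendropy

    tree = dendropy.Tree.get(data=source, schema="newick")
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(leaves) != 3:
        raise ValidationError(f"expected 3 taxa in the newick tree, found {len(leaves)}")
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if node is not tree.seed_node and len(children) == 2 and all(
            c.is_leaf() for c in children
        ):
            ingroup = tuple(c.taxon.label for c in children)
            (outgroup,) = set(leaves) - set(ingroup)
            return TriadTree(ingroup, outgroup)
    raise ValidationError("newick tree does not contain a two-taxon cherry")


# ---------------------------------------------------------------------------
# model (de)serialization


def model_to_dict(model: FittedTriadModel) -> dict:
    return {
        "family": model.family,
        "clock": model.clock,
        "ingroup": list(model.tree.ingroup),
        "outgroup": model.tree.outgroup,
        "root_distribution": model.root_distribution.tolist(),
        "edges": {
            name: {"rate_matrix": e.rate_matrix.tolist(), "duration": e.duration}
            for name, e in model.edges.items()
        },
        "gamma_shape": model.gamma_shape,
        "n_rate_bins": model.n_rate_bins,
        "log_likelihood": model.log_likelihood,
        "dof": model.dof,
    }


def model_from_dict(d: dict) -> FittedTriadModel:
    tree = TriadTree(tuple(d["ingroup"]), d["outgroup"])
    edges = {
        name: EdgeProcess(np.asarray(e["rate_matrix"]), float(e["duration"]))
        for name, e in d["edges"].items()
    }
    return FittedTriadModel(
        family=d["family"],
        tree=tree,
        root_distribution=np.asarray(d["root_distribution"]),
        edges=edges,
        gamma_shape=d.get("gamma_shape"),
        n_rate_bins=d.get("n_rate_bins", 4),
        log_likelihood=d.get("log_likelihood", np.nan),
        dof=d.get("dof", 0),
        clock=d.get("clock", False),
    )


def write_model_json(model: FittedTriadModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def read_model_json(path) -> FittedTriadModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of a batch triad analysis."""

    ingroup: tuple[str, str]
    outgroup: str
    families: tuple[str, ...] = (GTR, GTR_GAMMA, GENERAL)
    clock: bool = False
    bootstrap_reps: int = 0
    gof_alpha: float = 0.05
    apply_filters: bool = False
    min_length: int | None = DEFAULT_MIN_LENGTH
    seed: int | None = None

    @property
    def tree(self) -> TriadTree:
        return TriadTree(tuple(self.ingroup), self.outgroup)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d["ingroup"] = tuple(d["ingroup"])
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)


def _pair_key(a: str, b: str) -> str:
    return f"{a}:{b}"


def analyze_alignment(
    aln: TriadAlignment,
    config: PipelineConfig,
    name: str = "alignment",
    seed: int | None = None,
) -> dict:
    """Full analysis of one triad alignment: fits, diagnostics, distances.

    Returns a flat report record.  Numeric fields all trace back to the
    public operations of this package; nothing is recomputed downstream.
    """
    tree = config.tree
    counts = pattern_counts(aln, tree)
    order = tree.leaf_order
    pairs = [(order[0], order[1]), (order[0], order[2]), (order[1], order[2])]
    record: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "alignment": name,
        "n_sites": int(counts.sum()),
        "removed_columns": aln.removed_columns,
        "jsd": alignment_jsd(aln),
    }
    for leaf in order:
        record[f"gc.{leaf}"] = gc_content(aln.sequences[leaf])
    for a, b in pairs:
        J = empirical_joint(aln.sequences[a], aln.sequences[b])
        key = _pair_key(a, b)
        try:
            record[f"dpara.{key}"] = paralinear_distance(J)
        except SaturationError:
            record[f"dpara.{key}"] = None
        try:
            record[f"dlogdet.{key}"] = logdet_distance(J)
        except SaturationError:
            record[f"dlogdet.{key}"] = None

    fits = sequential_fit(
        counts, tree, families=config.families, clock_suite=config.clock, seed=seed
    )
    dist_label = {GTR: "dGTR", GTR_GAMMA: "dGTRG", GENERAL: "dENS"}
    for fit_name, fit in fits.items():
        prefix = fit_name
        record[f"{prefix}.lnL"] = fit.log_likelihood
        record[f"{prefix}.dof"] = fit.dof
        record[f"{prefix}.aic"] = aic(fit)
        diag = diagnose_fit(
            fit,
            counts,
            n_bootstrap=(config.bootstrap_reps if not fit.clock else 0),
            seed=seed,
        )
        record[f"{prefix}.G"] = diag.g_statistic
        record[f"{prefix}.dlc"] = all(diag.dlc_pass.values())
        record[f"{prefix}.unique_mapping"] = all(diag.unique_mapping_pass.values())
        if diag.bootstrap_p is not None:
            record[f"{prefix}.gof_p"] = diag.bootstrap_p
        if not fit.clock:
            label = dist_label[fit.family]
            for a, b in pairs:
                record[f"{label}.{_pair_key(a, b)}"] = ens_path_distance(fit, a, b)
            record[f"{label}.ratio"] = edge_length_ratio(fit, order[0], order[1])
    if config.clock:
        for family in config.families:
            free, clk = fits.get(family), fits.get(f"{family}-clock")
            if free is not None and clk is not None:
                record[f"{family}.clock_p"] = clock_lrt(clk, free)
    if config.bootstrap_reps and config.apply_filters:
        general_p = record.get(f"{GENERAL}.gof_p")
        record["excluded"] = bool(general_p is not None and general_p < config.gof_alpha)
    return record


def run_pipeline(alignments, config: PipelineConfig):
    """Analyze a batch of alignments, yielding one report record each.

    ``alignments`` is an iterable of FASTA paths or of
    ``(name, TriadAlignment)`` pairs.  Per-alignment failures are recorded
    in the report (with an ``error`` field) and never abort the batch.
    Records are deterministic for a fixed ``config.seed``.
    """
    alignments = list(alignments)
    ss = np.random.SeedSequence(config.seed)
    for item, child in zip(alignments, ss.spawn(max(len(alignments), 1))):
        seed = int(child.generate_state(1)[0] % (2**31))
        if isinstance(item, tuple):
            name, aln = item
        else:
            name = str(item)
            try:
                aln = read_triad_fasta(
                    item, config.tree.leaf_order, min_length=config.min_length
                )
            except (ValidationError, OSError) as exc:
                logger.error("%s: %s", item, exc)
                yield {
                    "schema_version": REPORT_SCHEMA_VERSION,
                    "alignment": name,
                    "error": str(exc),
                }
                continue
        try:
            yield analyze_alignment(aln, config, name=name, seed=seed)
        except (FitError, ValidationError) as exc:
            logger.error("%s: %s", name, exc)
            yield {
                "schema_version": REPORT_SCHEMA_VERSION,
                "alignment": name,
                "error": str(exc),
            }


def write_report_jsonl(records, path) -> None:
    with open(path, "a") as fh:
        for record in records:
            fh.write(json.dumps(record) + "\n")


def write_report_tsv(records, path) -> None:
    records = list(records)
    keys: list[str] = []
    for record in records:
        for key in record:
            if key not in keys:
                keys.append(key)
    new_file = not Path(path).exists() or Path(path).stat().st_size == 0
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys, delimiter="\t")
        if new_file:
            writer.writeheader()
        writer.writerows(records)
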