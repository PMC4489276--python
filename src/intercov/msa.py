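"""Alignment containers, trimming/coverage rules, Hobohm-1 clustering and
cluster-based sequence weights.

Conventions fixed here and used everywhere downstream:

* the first record of an alignment is the reference sequence;
* internal coordinates are 0-based half-open, user-facing reports are
  1-based in reference numbering;
* percent identity = matches / columns where *both* sequences are non-gap
  ('X' never matches, but does occupy a comparable column);
* sequences covering strictly less than ``min_fraction`` of the reference
  length are removed (a sequence at exactly the boundary is kept).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, encode, normalize_residues


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: identifier, residues, optional NCBI taxID."""

    id: str
    residues: str
    taxid: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if self.taxid is not None and self.taxid < 0:
            raise ValueError(f"record {self.id!r}: taxid must be non-negative")


@dataclass
class Msa:
    """Rectangular gapped alignment; ``records[0]`` is the reference."""

    records: list[SequenceRecord]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        L = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != L:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {L}"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def reference(self) -> SequenceRecord:
        return self.records[0]

    @property
    def taxids(self) -> list[int | None]:
        return [r.taxid for r in self.records]

    def codes(self) -> np.ndarray:
        """(n, L) int8 matrix; 0-19 aa, 20 gap, 21 unknown. Cached."""
        if self._codes is None:
            self._codes = encode([r.residues for r in self.records])
        return self._codes


@dataclass(frozen=True)
class ClusterAssignment:
    """Hobohm-1 result: one cluster id per record, in record order."""

    cluster_ids: np.ndarray
    representative_indices: list[int]
    identity_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.representative_indices)


@dataclass(frozen=True)
class SequenceWeights:
    """Per-record weights and the effective sequence count Meff."""

    weights: np.ndarray
    meff: float


def read_fasta_msa(path, taxid_pattern: str | None = None) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Residues are upper-cased, '.' becomes '-', and any non-standard letter
    becomes 'X'. When ``taxid_pattern`` is given, its first capture group is
    applied to each full header to extract the record's taxID (records whose
    header does not match simply get no taxID).
    """
    pattern = re.compile(taxid_pattern) if taxid_pattern else None
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxid = None
        if pattern is not None:
            m = pattern.search(rec.description)
            if m:
                taxid = int(m.group(1))
        records.append(
            SequenceRecord(rec.id, normalize_residues(str(rec.seq)), taxid)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Msa(records)


def write_fasta_msa(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for rec in msa.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def trim_to_reference(msa: Msa) -> tuple[Msa, np.ndarray]:
    """Remove every column where the reference has a gap.

    Returns the trimmed alignment together with the array of kept (old)
    column indices; position ``k`` of the array is the old index of new
    column ``k``.
    """
    ref = msa.reference.residues
    keep = np.array([c != GAP for c in ref], dtype=bool)
    if not keep.any():
        raise ValueError("empty reference: reference sequence is all gaps")
    kept_cols = np.flatnonzero(keep)
    if keep.all():
        return Msa(list(msa.records)), kept_cols
    records = [
        SequenceRecord(r.id, "".join(r.residues[i] for i in kept_cols), r.taxid)
        for r in msa.records
    ]
    return Msa(records), kept_cols


def filter_coverage(msa: Msa, min_fraction: float = 0.5) -> Msa:
    """Drop records covering less than ``min_fraction`` of the alignment.

    Coverage = non-gap residues / alignment length, measured after the
    alignment has been trimmed to the reference, so the denominator is the
    reference length. Removal is strict (coverage exactly at the boundary is
    kept) and the reference itself is never removed.
    """
    L = msa.length
    kept = [msa.records[0]]
    for rec in msa.records[1:]:
        coverage = (L - rec.residues.count(GAP)) / L
        if coverage >= min_fraction:
            kept.append(rec)
    return Msa(kept)


def percent_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Fraction of matching residues over columns where both are non-gap.

    'X' occupies a comparable column but never matches. Returns 0.0 when no
    column is comparable.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError("percent_identity requires equal-length sequences")
    ca, cb = encode([sa])[0], encode([sb])[0]
    both = (ca != 20) & (cb != 20)
    n = int(both.sum())
    if n == 0:
        return 0.0
    matches = int(((ca == cb) & both & (ca != 21)).sum())
    return matches / n


def _identity_matrix(codes: np.ndarray) -> np.ndarray:
    """All-against-all percent identity for an encoded alignment.

    Uses one-hot matmuls: match counts from the 20-state channels (so 'X'
    never matches) and comparable-column counts from the non-gap mask.
    """
    n, L = codes.shape
    onehot = np.zeros((n, L, 20), dtype=np.float32)
    aa = codes < 20
    rows, cols = np.nonzero(aa)
    onehot[rows, cols, codes[rows, cols]] = 1.0
    flat = onehot.reshape(n, L * 20)
    matches = flat @ flat.T
    nongap = (codes != 20).astype(np.float32)
    comparable = nongap @ nongap.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(comparable > 0, matches / np.maximum(comparable, 1), 0.0)
    return ident


def hobohm1(msa: Msa, identity_threshold: float = 0.62) -> ClusterAssignment:
    """Greedy Hobohm-1 clustering in record order.

    Each record joins the first existing cluster whose representative is at
    least ``identity_threshold`` identical to it, otherwise it founds a new
    cluster with itself as representative. Deterministic given record order.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ident = _identity_matrix(msa.codes())
    cluster_ids = np.empty(msa.n_records, dtype=np.int64)
    reps: list[int] = []
    for r in range(msa.n_records):
        assigned = False
        for cid, rep in enumerate(reps):
            if ident[r, rep] >= identity_threshold - 1e-12:
                cluster_ids[r] = cid
                assigned = True
                break
        if not assigned:
            cluster_ids[r] = len(reps)
            reps.append(r)
    return ClusterAssignment(cluster_ids, reps, identity_threshold)


def cluster_weights(clusters: ClusterAssignment) -> SequenceWeights:
    """Weight 1/|cluster| per record; Meff = number of clusters (exactly)."""
    sizes = np.bincount(clusters.cluster_ids, minlength=clusters.n_clusters)
    weights = 1.0 / sizes[clusters.cluster_ids]
    return SequenceWeights(weights, float(clusters.n_clusters))


def write_cluster_report(msa: Msa, clusters: ClusterAssignment,
                         weights: SequenceWeights, path) -> None:
    """TSV report (record_id, cluster_id, weight) plus a Meff header line."""
    with open(path, "w") as fh:
        fh.write(f"# identity_threshold\t{clusters.identity_threshold}\n")
        fh.write(f"# n_clusters\t{clusters.n_clusters}\n")
        fh.write("record_id\tcluster_id\tweight\n")
        for rec, cid, w in zip(msa.records, clusters.cluster_ids,
                               weights.weights):
            fh.write(f"{rec.id}\t{cid}\t{w:.6g}\n")
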