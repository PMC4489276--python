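"""Construction of taxID-paired concatenated alignments for 2-6 proteins.

Homolog hit tables (BLAST tabular, extended with a ``staxids`` column and a
gapped subject alignment in query coordinates) are reduced to one sequence
per taxID per protein — the paralog-resolution rule keeps the hit with the
lowest E-value, then the highest bit-score, then the lexicographically
smallest subject id — and sequences sharing a taxID across all proteins are
concatenated row-wise. The first row is always the concatenation of the
reference sequences; the remaining rows are ordered by ascending taxID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import (Msa, SequenceRecord, filter_coverage, trim_to_reference)
from .alphabet import normalize_residues

MAX_PROTEINS = 6
MAX_TOTAL_LENGTH = 2000

#: documented defaults for the user's own homolog search (not executed here)
RECOMMENDED_SEARCH = {"evalue_threshold": 1e-5, "psiblast_iterations": 3}

HIT_TABLE_COLUMNS = ["qseqid", "sseqid", "staxids", "evalue", "bitscore", "sseq"]


@dataclass(frozen=True)
class HitRecord:
    """One homolog hit of a query protein, aligned in query coordinates."""

    query_index: int
    subject_id: str
    taxid: int
    evalue: float
    bitscore: float
    aligned_seq: str

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.taxid <= 0:
            raise ValueError("taxid must be positive")


@dataclass
class PairedMsa:
    """Concatenated alignment plus the column ranges of each protein.

    ``segments`` is an ordered list of (protein_label, start, end) in
    0-based half-open column coordinates, contiguously partitioning [0, L).
    """

    msa: Msa
    segments: list[tuple[str, int, int]]

    def __post_init__(self):
        if not 2 <= len(self.segments) <= MAX_PROTEINS:
            raise ValueError("a paired MSA must have between 2 and "
                             f"{MAX_PROTEINS} protein segments")
        pos = 0
        for label, start, end in self.segments:
            if start != pos or end <= start:
                raise ValueError("segments must contiguously partition the "
                                 "alignment columns")
            pos = end
        if pos != self.msa.length:
            raise ValueError("segments do not cover the alignment length")

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]

    def segment_of(self, column: int) -> str:
        for label, start, end in self.segments:
            if start <= column < end:
                return label
        raise IndexError(f"column {column} outside all segments")


def read_hit_table(path, query_index: int = 0,
                   subject_fasta: dict[str, str] | None = None) -> list[HitRecord]:
    """Read an extended BLAST tabular file into hit records.

    Expected columns (no header, tab-separated): qseqid, sseqid, staxids,
    evalue, bitscore, sseq — the outfmt-6 core plus the subject sequence
    aligned in query coordinates. When the sseq column is absent, the gapped
    subject sequences are looked up by sseqid in ``subject_fasta``.
    Multi-valued staxids cells (semicolon-separated) replicate the hit once
    per taxID.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] not in (5, 6):
        raise ValueError(f"hit table {path} must have 5 or 6 columns, got "
                         f"{df.shape[1]}")
    df.columns = HIT_TABLE_COLUMNS[: df.shape[1]]
    hits = []
    for row in df.itertuples(index=False):
        if df.shape[1] == 6:
            seq = row.sseq
        else:
            if subject_fasta is None or row.sseqid not in subject_fasta:
                raise ValueError(f"no aligned sequence for subject "
                                 f"{row.sseqid!r}")
            seq = subject_fasta[row.sseqid]
        for taxid in str(row.staxids).split(";"):
            taxid = taxid.strip()
            if not taxid:
                continue
            hits.append(HitRecord(query_index, row.sseqid, int(taxid),
                                  float(row.evalue), float(row.bitscore),
                                  normalize_residues(seq)))
    return hits


def best_hit_per_taxid(hits: list[HitRecord]) -> dict[int, HitRecord]:
    """Keep one hit per taxID: lowest E-value, then highest bit-score, then
    lexicographically smallest subject id. Deterministic regardless of the
    input row order."""
    if hits:
        qi = hits[0].query_index
        if any(h.query_index != qi for h in hits):
            raise ValueError("all hits must share one query_index")
    best: dict[int, HitRecord] = {}
    for hit in hits:
        cur = best.get(hit.taxid)
        if cur is None or _hit_order_key(hit) < _hit_order_key(cur):
            best[hit.taxid] = hit
    return best


def _hit_order_key(h: HitRecord):
    return (h.evalue, -h.bitscore, h.subject_id)


def build_paired_msa(
    per_protein: list[tuple[SequenceRecord, dict[int, HitRecord]]],
    labels: list[str] | None = None,
    min_coverage: float = 0.5,
    enforce_length_limit: bool = False,
) -> PairedMsa:
    """Concatenate one sequence per common taxID across 2-6 proteins.

    Rows are the ascending-taxID intersection of the per-protein taxID sets;
    the first row is the concatenated references. Gap-trimming to the
    reference and the coverage filter are applied to the concatenated
    alignment, with the segment map updated through the kept-column map.
    """
    if not 2 <= len(per_protein) <= MAX_PROTEINS:
        raise ValueError(f"between 2 and {MAX_PROTEINS} proteins required, "
                         f"got {len(per_protein)}")
    if labels is None:
        labels = [ref.id for ref, _ in per_protein]
    for ref, selected in per_protein:
        if "-" in ref.residues:
            raise ValueError(f"reference {ref.id!r} must be gap-free")
        for hit in selected.values():
            if len(hit.aligned_seq) != len(ref.residues):
                raise ValueError(
                    f"hit {hit.subject_id!r}: aligned_seq length "
                    f"{len(hit.aligned_seq)} != reference length "
                    f"{len(ref.residues)}")

    total_len = sum(len(ref.residues) for ref, _ in per_protein)
    if total_len > MAX_TOTAL_LENGTH:
        msg = (f"total reference length {total_len} exceeds the "
               f"{MAX_TOTAL_LENGTH}-residue guard")
        if enforce_length_limit:
            raise ValueError(msg)
        warnings.warn(msg)

    common = set(per_protein[0][1])
    for _, selected in per_protein[1:]:
        common &= set(selected)
    if not common:
        raise ValueError("no common taxa: the taxID intersection across "
                         "proteins is empty")

    records = [SequenceRecord(
        "reference|" + "|".join(ref.id for ref, _ in per_protein),
        "".join(ref.residues for ref, _ in per_protein))]
    for taxid in sorted(common):
        chosen = [selected[taxid] for _, selected in per_protein]
        rid = f"{taxid}|" + "|".join(h.subject_id for h in chosen)
        records.append(SequenceRecord(
            rid, "".join(h.aligned_seq for h in chosen), taxid))

    segments = []
    pos = 0
    for label, (ref, _) in zip(labels, per_protein):
        segments.append((label, pos, pos + len(ref.residues)))
        pos += len(ref.residues)

    return _trim_and_filter(Msa(records), segments, min_coverage)


def validate_user_paired_msas(msas: list[Msa],
                              labels: list[str] | None = None,
                              min_coverage: float = 0.5) -> PairedMsa:
    """Concatenate user-supplied per-protein MSAs whose rows are matched.

    The alignments must have equal record counts, and when taxIDs are
    present on both sides of a row they must agree.
    """
    if len(msas) < 2:
        raise ValueError("at least two protein alignments are required")
    if len(msas) > MAX_PROTEINS:
        raise ValueError(f"at most six proteins are supported, got {len(msas)}")
    n = msas[0].n_records
    for k, msa in enumerate(msas[1:], start=2):
        if msa.n_records != n:
            raise ValueError(f"alignment {k} has {msa.n_records} records, "
                             f"expected {n}")
    for row in range(n):
        tids = {m.records[row].taxid for m in msas
                if m.records[row].taxid is not None}
        if len(tids) > 1:
            raise ValueError(f"taxid mismatch at row {row + 1}: "
                             f"{sorted(tids)}")
    if labels is None:
        labels = [m.reference.id for m in msas]
    records = []
    for row in range(n):
        taxid = next((m.records[row].taxid for m in msas
                      if m.records[row].taxid is not None), None)
        rid = "|".join(m.records[row].id for m in msas)
        records.append(SequenceRecord(
            rid, "".join(m.records[row].residues for m in msas), taxid))
    segments = []
    pos = 0
    for label, msa in zip(labels, msas):
        segments.append((label, pos, pos + msa.length))
        pos += msa.length
    return _trim_and_filter(Msa(records), segments, min_coverage)


def _trim_and_filter(msa: Msa, segments, min_coverage: float) -> PairedMsa:
    trimmed, kept_cols = trim_to_reference(msa)
    new_segments = []
    for label, start, end in segments:
        in_seg = (kept_cols >= start) & (kept_cols < end)
        n_kept = int(in_seg.sum())
        if n_kept == 0:
            raise ValueError(f"segment {label!r} lost all columns in "
                             "reference trimming")
        offset = int(np.searchsorted(kept_cols, start))
        new_segments.append((label, offset, offset + n_kept))
    filtered = filter_coverage(trimmed, min_coverage)
    return PairedMsa(filtered, new_segments)


def write_paired_msa(paired: PairedMsa, fasta_path, segments_path=None) -> None:
    """Write the paired alignment as FASTA plus a segments sidecar TSV.

    The sidecar reports 1-based inclusive column ranges per protein.
    """
    with open(fasta_path, "w") as fh:
        for rec in paired.msa.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    if segments_path is not None:
        with open(segments_path, "w") as fh:
            fh.write("protein_label\tstart\tend\n")
            for label, start, end in paired.segments:
                fh.write(f"{label}\t{start + 1}\t{end}\n")


def read_segments_tsv(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.protein_label), int(r.start) - 1, int(r.end))
            for r in df.itertuples(index=False)]
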