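"""Evaluation of covariation predictions against a protein structure.

A contact map over paired-alignment reference positions is derived from a
PDB structure at a Cα distance threshold (strictly below 12 Å by default),
after mapping each reference protein segment onto its structure chain by
global sequence alignment. Predictions are then scored by precision among
the top-k ranked pairs and by ROC AUC, either over interprotein pairs,
intraprotein pairs, or all pairs. Positions without a structural mapping
are excluded from the metrics (and their count reported), never counted as
non-contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from sklearn.metrics import roc_auc_score

from .compare import _class_matches


@dataclass
class ChainCoordinates:
    """Cα trace of one chain: residue numbers, one-letter codes, coords."""

    chain_id: str
    residue_numbers: list[int]
    sequence: str
    ca_xyz: np.ndarray           # (n_res, 3) in Å

    def __post_init__(self):
        nums = self.residue_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"chain {self.chain_id}: residue numbers must "
                             "be strictly increasing")
        if len(nums) != len(self.sequence) or len(nums) != len(self.ca_xyz):
            raise ValueError("inconsistent chain record lengths")


@dataclass
class ContactMap:
    """Boolean contact matrix over reference positions.

    ``mapped`` flags positions with a structural mapping; only pairs with
    both endpoints mapped carry meaning, all other entries are False.
    """

    contacts: np.ndarray         # (L, L) bool
    mapped: np.ndarray           # (L,) bool
    threshold: float
    residue_numbers: dict[int, tuple[str, int]]   # column -> (chain, resnum)
    distances: np.ndarray | None = None


def load_structure_chains(pdb_path, chain_ids) -> list[ChainCoordinates]:
    """Parse Cα coordinates for the requested chains of a PDB file.

    First model only; HETATM residues skipped; disordered atoms resolved to
    the highest-occupancy location (first on ties); residues without a Cα
    are excluded with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    available = {c.id for c in model}
    out = []
    for chain_id in chain_ids:
        if chain_id not in available:
            raise ValueError(f"chain {chain_id!r} not found; available: "
                             f"{sorted(available)}")
        chain = model[chain_id]
        numbers, letters, coords = [], [], []
        for residue in chain:
            hetflag, resnum, _ = residue.id
            if hetflag != " ":
                continue
            if "CA" not in residue:
                warnings.warn(f"chain {chain_id} residue {resnum} has no "
                              "Cα; excluded")
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                alts = sorted(atom.disordered_get_list(),
                              key=lambda a: (-a.get_occupancy(),
                                             a.get_altloc()))
                atom = alts[0]
            numbers.append(resnum)
            letters.append(seq1(residue.get_resname(), undef_code="X"))
            coords.append(atom.get_coord())
        if not numbers:
            raise ValueError(f"chain {chain_id!r} has no usable residues")
        out.append(ChainCoordinates(chain_id, numbers, "".join(letters),
                                    np.asarray(coords, dtype=float)))
    return out


def map_reference_to_chain(reference_segment_seq: str,
                           chain: ChainCoordinates,
                           min_coverage: float = 0.3) -> dict[int, int]:
    """Map reference-segment columns to chain residue indices.

    Global alignment (match +1, mismatch 0, gap -1) of the ungapped
    reference segment against the chain's one-letter sequence; every
    aligned (non-gap vs non-gap) column defines a mapping, so isolated
    point mutations still map. Keys are 0-based segment columns, values
    are indices into the chain's residue list.
    """
    if not reference_segment_seq or not chain.sequence:
        raise ValueError("empty sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(reference_segment_seq, chain.sequence)[0]
    mapping: dict[int, int] = {}
    n_identical = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for offset in range(t1 - t0):
            mapping[t0 + offset] = q0 + offset
            if reference_segment_seq[t0 + offset] == \
                    chain.sequence[q0 + offset]:
                n_identical += 1
    # the wrong-chain guard counts identical aligned columns, so that a
    # chain of unrelated sequence fails even when it aligns end to end
    coverage = n_identical / len(reference_segment_seq)
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of the reference segment matches "
            f"chain {chain.chain_id!r} — wrong chain?")
    return mapping


def contact_map(segment_mappings: list[dict[int, int]],
                chains: list[ChainCoordinates],
                segments: list[tuple[str, int, int]],
                threshold: float = 12.0) -> ContactMap:
    """Contact map over concatenated reference positions.

    contact(i, j) is true iff both positions are structurally mapped and
    their Cα Euclidean distance is strictly below ``threshold`` Å.
    """
    if len(segment_mappings) != len(chains) or len(chains) != len(segments):
        raise ValueError("one mapping and one chain per segment required")
    L = segments[-1][2]
    coords = np.full((L, 3), np.nan)
    residue_numbers: dict[int, tuple[str, int]] = {}
    for mapping, chain, (label, start, end) in zip(segment_mappings, chains,
                                                   segments):
        for col, res_idx in mapping.items():
            if not 0 <= col < end - start:
                raise ValueError(f"mapped column {col} outside segment "
                                 f"{label!r}")
            coords[start + col] = chain.ca_xyz[res_idx]
            residue_numbers[start + col] = (chain.chain_id,
                                            chain.residue_numbers[res_idx])
    mapped = ~np.isnan(coords[:, 0])
    if mapped.sum() < 2:
        raise ValueError("fewer than 2 mapped positions")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    contacts = (dist < threshold) & mapped[:, None] & mapped[None, :]
    np.fill_diagonal(contacts, False)
    return ContactMap(contacts, mapped, threshold, residue_numbers, dist)


def evaluate_predictions(ranked: pd.DataFrame, cmap: ContactMap,
                         class_filter: str = "both",
                         k: int | None = None) -> dict:
    """Precision@k and ROC AUC of a ranking against a contact map.

    The ranking is filtered to ``class_filter`` ('inter', 'intra', 'both')
    and to pairs with both endpoints mapped; precision@k is the contact
    fraction among the first k such pairs, and the AUC treats contacts as
    positives over all such pairs.
    """
    mask = ranked["cls"].map(lambda c: _class_matches(c, class_filter))
    sub = ranked[mask]
    both_mapped = np.array([cmap.mapped[i] and cmap.mapped[j]
                            for i, j in zip(sub["i"], sub["j"])], dtype=bool)
    n_skipped = int((~both_mapped).sum())
    sub = sub[both_mapped]
    if len(sub) == 0:
        raise ValueError("no mapped pairs to evaluate")
    is_contact = np.array([cmap.contacts[i, j]
                           for i, j in zip(sub["i"], sub["j"])], dtype=bool)
    out = {"class_filter": class_filter, "n_pairs": int(len(sub)),
           "n_skipped_unmapped": n_skipped,
           "n_contacts": int(is_contact.sum())}
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        topk = is_contact[:min(k, len(sub))]
        out["k"] = int(k)
        out["precision_at_k"] = float(topk.mean())
    n_pos = int(is_contact.sum())
    if n_pos == 0 or n_pos == len(sub):
        raise ValueError("AUC undefined: need both contacts and "
                         "non-contacts among evaluated pairs")
    out["roc_auc"] = float(roc_auc_score(is_contact,
                                         sub["score"].to_numpy()))
    return out


def annotate_pairs(ranked: pd.DataFrame, cmap: ContactMap) -> pd.DataFrame:
    """Ranking annotated with structural distance and contact status."""
    dist, contact = [], []
    for i, j in zip(ranked["i"], ranked["j"]):
        if cmap.mapped[i] and cmap.mapped[j]:
            dist.append(float(cmap.distances[i, j]))
            contact.append(bool(cmap.contacts[i, j]))
        else:
            dist.append(np.nan)
            contact.append(False)
    out = ranked.copy()
    out["distance_A"] = dist
    out["contact"] = contact
    return out
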