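"""Seeded generators for every input class the toolkit consumes.

These are first-class, deterministic simulators (not canned files): paired
alignments sampled from a pairwise Potts model with planted cross-boundary
couplings, independent-column null alignments, crafted homolog hit tables
with controlled taxID/paralog/E-value structure, and minimal Cα-only PDB
files with known contact maps. They exist so that statistical claims about
the scoring methods can be tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20
from .msa import Msa, SequenceRecord
from .pairing import PairedMsa


@dataclass
class PlantedPottsSpec:
    """Sampling plan for a paired Potts alignment with planted couplings.

    The coupling of a planted pair (i, j) is Ising-like,
    e_ij(a, b) = strength·[a = b], so a single scalar controls the signal
    and the q=2 case has a closed-form same-state probability.
    """

    L: int = 40
    q: int = 8
    n_sequences: int = 2000
    segment_split: int = 20
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)
    coupling_strength: float = 1.5
    gibbs_sweeps: int = 50
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.segment_split < self.L:
            raise ValueError("segment_split must lie strictly inside [0, L]")
        if self.q > len(AA20):
            raise ValueError(f"q must be at most {len(AA20)}")
        if len(set(self.planted_pairs)) != len(self.planted_pairs):
            raise ValueError("planted pairs must be distinct")
        for i, j in self.planted_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L and i != j):
                raise ValueError(f"invalid planted pair ({i}, {j})")


def cross_segment_pairs(spec_L: int, split: int, n_pairs: int,
                        seed: int) -> list[tuple[int, int]]:
    """Draw planted cross-boundary pairs with disjoint endpoints."""
    rng = np.random.default_rng(seed)
    if n_pairs > min(split, spec_L - split):
        raise ValueError("not enough positions for disjoint planted pairs")
    left = rng.choice(split, size=n_pairs, replace=False)
    right = rng.choice(np.arange(split, spec_L), size=n_pairs, replace=False)
    return [(int(i), int(j)) for i, j in zip(left, right)]


def sample_potts_msa(spec: PlantedPottsSpec) -> tuple[PairedMsa,
                                                      list[tuple[int, int]]]:
    """Gibbs-sample a paired alignment from the planted Potts model.

    One independent chain per sequence; ``burn_in + gibbs_sweeps``
    sequential sweeps are run and the final state is the sample, so rows
    are mutually independent. States are written as the first q amino
    acids; taxIDs are 1..n and the first chain doubles as the reference
    row. Bit-reproducible given the sampling plan (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n, L, q = spec.n_sequences, spec.L, spec.q
    partners: list[list[tuple[int, float]]] = [[] for _ in range(L)]
    for i, j in spec.planted_pairs:
        partners[i].append((j, spec.coupling_strength))
        partners[j].append((i, spec.coupling_strength))

    x = rng.integers(0, q, size=(n, L))
    total_sweeps = spec.burn_in + spec.gibbs_sweeps
    rows = np.arange(n)
    for _ in range(total_sweeps):
        for site in range(L):
            if partners[site]:
                logits = np.zeros((n, q))
                for j, strength in partners[site]:
                    logits[rows, x[:, j]] += strength
                p = np.exp(logits - logits.max(axis=1, keepdims=True))
                p /= p.sum(axis=1, keepdims=True)
                cdf = np.cumsum(p, axis=1)
                u = rng.random(n)
                x[:, site] = (cdf < u[:, None]).sum(axis=1)
            else:
                x[:, site] = rng.integers(0, q, size=n)

    letters = np.array(list(AA20[:q]))
    records = []
    for r in range(n):
        seq = "".join(letters[x[r]])
        records.append(SequenceRecord(f"seq{r + 1}", seq, taxid=r + 1))
    segments = [("A", 0, spec.segment_split), ("B", spec.segment_split, L)]
    paired = PairedMsa(Msa(records), segments)
    planted = [(min(i, j), max(i, j)) for i, j in spec.planted_pairs]
    return paired, sorted(planted)


def iid_column_msa(n: int, L: int, q: int, seed: int,
                   segment_split: int | None = None) -> PairedMsa:
    """Null alignment: every column i.i.d. uniform over q states."""
    split = segment_split if segment_split is not None else L // 2
    spec = PlantedPottsSpec(L=L, q=q, n_sequences=n, segment_split=split,
                            planted_pairs=[], coupling_strength=0.0,
                            gibbs_sweeps=0, burn_in=1, seed=seed)
    paired, _ = sample_potts_msa(spec)
    return paired


# ---------------------------------------------------------------------------
# hit-table fixtures with hand-computed expected outputs


@dataclass
class HitFixture:
    """Crafted hit tables plus the hand-computed expected paired MSA."""

    plan: str
    references: list[SequenceRecord]
    hit_tables: list[str]                    # extended BLAST tabular text
    expected_fasta: str | None               # golden paired-MSA FASTA
    expected_segments: list[tuple[str, int, int]] | None
    expect_error: str | None = None


def _tsv(rows):
    return "".join("\t".join(str(v) for v in row) + "\n" for row in rows)


HIT_FIXTURE_PLANS = ("paralog_evalue", "bitscore_tie", "empty_intersection",
                     "three_proteins")


def make_hit_fixture(plan: str) -> HitFixture:
    """Build one of the scripted pairing scenarios.

    Every expected output below is written out by hand from the pairing
    rules (best E-value, then bit-score, then lexicographic subject id;
    rows = ascending-taxID intersection; reference row first), never by
    running the pairing code.
    """
    if plan == "paralog_evalue":
        # taxid 7 has two protein-A paralogs; the lower E-value one wins
        ref_a = SequenceRecord("protA", "MKLV")
        ref_b = SequenceRecord("protB", "ADERG")
        hits_a = _tsv([
            ("protA", "A7b", 7, 1e-8, 180.0, "MKAV"),
            ("protA", "A7a", 7, 1e-10, 170.0, "MKIV"),
            ("protA", "A9", 9, 1e-6, 150.0, "MQLV"),
        ])
        hits_b = _tsv([
            ("protB", "B7", 7, 1e-9, 210.0, "ADDRG"),
            ("protB", "B9", 9, 1e-7, 190.0, "ASERG"),
        ])
        expected = (">reference|protA|protB\nMKLVADERG\n"
                    ">7|A7a|B7\nMKIVADDRG\n"
                    ">9|A9|B9\nMQLVASERG\n")
        return HitFixture(plan, [ref_a, ref_b], [hits_a, hits_b], expected,
                          [("protA", 0, 4), ("protB", 4, 9)])

    if plan == "bitscore_tie":
        # equal E-values: higher bit-score wins (A5hi); full tie on
        # protein B: lexicographically smaller subject id wins (A2 < B1)
        ref_a = SequenceRecord("protA", "MKLV")
        ref_b = SequenceRecord("protB", "ADERG")
        hits_a = _tsv([
            ("protA", "A5lo", 5, 1e-8, 150.0, "MRLV"),
            ("protA", "A5hi", 5, 1e-8, 200.0, "MKIV"),
        ])
        hits_b = _tsv([
            ("protB", "B1", 5, 1e-9, 210.0, "ADDRG"),
            ("protB", "A2", 5, 1e-9, 210.0, "ASERG"),
        ])
        expected = (">reference|protA|protB\nMKLVADERG\n"
                    ">5|A5hi|A2\nMKIVASERG\n")
        return HitFixture(plan, [ref_a, ref_b], [hits_a, hits_b], expected,
                          [("protA", 0, 4), ("protB", 4, 9)])

    if plan == "empty_intersection":
        ref_a = SequenceRecord("protA", "MKLV")
        ref_b = SequenceRecord("protB", "ADERG")
        hits_a = _tsv([
            ("protA", "A1", 1, 1e-8, 150.0, "MRLV"),
            ("protA", "A2", 2, 1e-9, 160.0, "MKIV"),
        ])
        hits_b = _tsv([
            ("protB", "B3", 3, 1e-9, 210.0, "ADDRG"),
            ("protB", "B4", 4, 1e-7, 190.0, "ASERG"),
        ])
        return HitFixture(plan, [ref_a, ref_b], [hits_a, hits_b], None, None,
                          expect_error="no common taxa")

    if plan == "three_proteins":
        # taxid sets {1..5}, {2,3,5,6}, {1,2,3,5,9,11}: 3-way
        # intersection {2, 3, 5} -> reference row + 3 paired rows
        ref_a = SequenceRecord("protA", "MKL")
        ref_b = SequenceRecord("protB", "ADER")
        ref_c = SequenceRecord("protC", "GHWKV")
        hits_a = _tsv([("protA", f"A{t}", t, 1e-9, 100.0 + t, s)
                       for t, s in [(1, "MRL"), (2, "MKI"), (3, "MQL"),
                                    (4, "MKV"), (5, "MEL")]])
        hits_b = _tsv([("protB", f"B{t}", t, 1e-9, 100.0 + t, s)
                       for t, s in [(2, "ADDR"), (3, "ASER"), (5, "AQER"),
                                    (6, "ADEK")]])
        hits_c = _tsv([("protC", f"C{t}", t, 1e-9, 100.0 + t, s)
                       for t, s in [(1, "GHWKI"), (2, "GYWKV"), (3, "GHFKV"),
                                    (5, "GHWRV"), (9, "GHWKL"),
                                    (11, "AHWKV")]])
        expected = (">reference|protA|protB|protC\nMKLADERGHWKV\n"
                    ">2|A2|B2|C2\nMKIADDRGYWKV\n"
                    ">3|A3|B3|C3\nMQLASERGHFKV\n"
                    ">5|A5|B5|C5\nMELAQERGHWRV\n")
        return HitFixture(plan, [ref_a, ref_b, ref_c],
                          [hits_a, hits_b, hits_c], expected,
                          [("protA", 0, 3), ("protB", 3, 7),
                           ("protC", 7, 12)])

    raise ValueError(f"unknown hit-fixture plan {plan!r}; available: "
                     f"{HIT_FIXTURE_PLANS}")


# ---------------------------------------------------------------------------
# toy structures


def make_toy_structure(chains: list[tuple[str, list[tuple[float, float,
                                                          float]]]],
                       threshold: float = 12.0) -> tuple[str, np.ndarray]:
    """Minimal single-model, Cα-only PDB text with its expected contact map.

    Every residue is an alanine whose Cα sits at the stated coordinate (Å).
    The expected map is computed here by a direct double loop over all
    concatenated residues (strictly-below-threshold rule, False diagonal),
    independent of the structure module.
    """
    if not chains or any(not coords for _, coords in chains):
        raise ValueError("every chain needs at least one residue")
    lines = []
    serial = 0
    all_coords = []
    for chain_id, coords in chains:
        for resnum, (xx, yy, zz) in enumerate(coords, start=1):
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain_id}{resnum:4d}    "
                f"{xx:8.3f}{yy:8.3f}{zz:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append(f"TER   {serial + 1:5d}      ALA "
                     f"{chain_id}{len(coords):4d}")
        all_coords.extend(coords)
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    n = len(all_coords)
    expected = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            d = sum((all_coords[a][k] - all_coords[b][k]) ** 2
                    for k in range(3)) ** 0.5
            expected[a, b] = d < threshold
    return pdb_text, expected
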