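# intercov

Interprotein covariation analysis from taxID-paired multiple sequence
alignments: build the concatenated alignment for 2–6 proteins, score
residue covariation with three method families, compare and overlap the
methods, and evaluate predictions against structural contact maps.

## The problem

Residue pairs that coevolve across a protein family tend to be in spatial
contact, and pairs that coevolve *between* two proteins point at the
protein–protein interface. Measuring interprotein covariation requires an
alignment whose rows pair each organism's copy of protein A with the same
organism's copy of protein B (and C, …). `intercov` builds that alignment
by keeping one homolog per NCBI taxID — resolving paralogs by best search
E-value, then bit-score — and concatenating the sequences that share a
taxID. Because the available covariation estimators disagree on real data,
the package treats *method comparison* as a first-class operation: rank,
intersect and contrast the methods rather than trusting any single one.

## Methods

All scores are computed per pair of alignment columns (i, j), classified
as **intra**protein or **inter**protein by the segment each column belongs
to:

- **Corrected MI** — weighted amino-acid pair frequencies with a low-count
  correction; mutual information
  `MI(i,j) = Σ_ab f_ij(a,b) ln[f_ij(a,b) / (f_i(a) f_j(b))]`;
  the average product correction
  `APC(i,j) = MI̅_i · MI̅_j / MI̅` subtracted to strip background; z-scores
  against a null of column-shuffled alignments.
- **Mean-field DCA** — couplings `e = −C⁻¹` from the connected-correlation
  matrix of pseudocounted frequencies over 21 states (20 aa + gap), scored
  by direct information (DI): the mutual information of the two-site model
  `P(a,b) ∝ exp(e_ij(a,b)) μ_i(a) μ_j(b)` with auxiliary fields matched to
  the empirical marginals.
- **Pseudo-likelihood DCA** — L2-regularized Potts fit maximizing the
  weighted pseudo-likelihood, scored by APC-corrected Frobenius norms of
  the coupling blocks (gap state excluded, zero-sum gauge).
- **External scores** — methods not implemented here (e.g. sparse inverse
  covariance / PSICOV output) plug in through a plain `(i, j, score)` TSV
  and participate in every comparison.

Sequence redundancy is handled by Hobohm-1 clustering (weights 1/|cluster|)
for MI and by 80%-identity neighbourhood reweighting for the DCA methods.
Alignments are gap-trimmed to the reference sequence and rows covering
<50% of the reference length are removed.

## Worked example

Everything below uses synthetic inputs generated by the package itself, so
it runs offline in seconds:

```sh
# 1. crafted hit tables exercising the paralog-resolution rules
intercov fixtures --kind hits --plan three_proteins --out fx

# 2. pair: one row per taxID common to all three proteins
intercov pair --references fx/references.fasta \
    --hit-table fx/hits_protA.tsv --hit-table fx/hits_protB.tsv \
    --hit-table fx/hits_protC.tsv --out paired
# paired MSA: 4 rows x 12 columns

# 3. a Potts-sampled paired alignment with planted couplings, scored by MI
intercov fixtures --kind potts --seed 5 --out fx
intercov score --paired fx/potts_msa.fasta \
    --segments fx/potts_segments.tsv --method mi --out scores
# wrote scores for mi to scores
```

The score TSV starts:

```
pos_i  pos_j  res_i  res_j  protein_i  protein_j  zscore      raw_mi       mip          class
1      2      C      H      A          A          -3.9337223  0.050178729  -0.0094510595  intra:A
1      3      C      I      A          A          -2.2713497  0.048257703  -0.0054570552  intra:A
```

`paired/paired_msa.fasta` holds the reference row followed by the
taxID-paired rows (`>2|A2|B2|C2 …`), with `segments.tsv` recording which
1-based column range belongs to which protein. `scores/mi.tsv` lists every
pair with its raw MI, APC-corrected MI and z-score plus its inter/intra
class; the top z-scores on the Potts fixture are the planted
cross-boundary pairs. `intercov compare` then reports, for each method,
how deep into the overall ranking one must read to see n interprotein
links, the score densities per class, and the pairs on which up to four
methods agree; `intercov eval` maps the reference segments onto PDB chains
and reports precision@k and ROC AUC against the Cα contact map
(contact ⇔ distance strictly below 12 Å); `intercov plot` renders the
circos and rank-band matrix views.

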