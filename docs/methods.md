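# Methods

This note records the models implemented by `intercov`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not demonstrate.

## Paired alignment construction

A paired alignment joins, per organism, one homolog of each input protein
(2–6 proteins, ≤ 2000 total reference residues — the guard can be
overridden but the mean-field solver's dense inversion makes ~600 columns
a practical ceiling on 8 GB). Homologs arrive as extended BLAST tabular
hit tables (`qseqid sseqid staxids evalue bitscore sseq`, subject aligned
in query coordinates); running the search itself is out of scope, and the
documented defaults for the user's own search are an E-value threshold of
1e-5 with 3 PSI-BLAST iterations. Per protein and per taxID one hit is
kept: lowest E-value, then highest bit-score (the closest hit as an
orthology proxy), then — purely to make the selection a total order —
lexicographically smallest subject id. Multi-valued `staxids` cells
replicate the hit once per taxID. Rows are the ascending-taxID
intersection of the per-protein taxID sets; the reference row (the
concatenated query sequences) always comes first. Ascending-taxID row
order is a package convention; no downstream score depends on row order
(verified by the row-permutation invariance test).

After concatenation the alignment is gap-trimmed to the reference (every
column where the reference has a gap is dropped from all rows) and rows
covering strictly less than 50% of the reference length are removed — the
boundary case is kept. Users with a better orthology assignment can
instead supply per-protein alignments with matched rows; these are
validated (equal row counts, row-wise taxID agreement) and concatenated
unchanged.

## Alphabets and redundancy weighting

Residues are the 20 amino acids plus gap `-` and unknown `X`. Percent
identity is matches over columns where both sequences are non-gap; `X`
occupies a comparable column but never matches. Two weighting schemes are
used, matching each method family's lineage:

- **Hobohm-1 clustering** (MI, reporting): greedy single pass in record
  order; a record joins the first cluster whose representative is ≥ 62%
  identical, else founds a new one. Weights are 1/|cluster| and
  Meff = number of clusters, exactly. The 62% default is the corrected-MI
  lineage convention and is exposed as a parameter.
- **Neighbourhood reweighting** (DCA): w_r = 1/#{s : identity(r,s) ≥ 0.8},
  Meff = Σ w_r — the standard DCA constants.

For MI, gaps and `X` contribute no counts (a pair is counted only when
both positions are non-gap). For DCA the gap is an explicit 21st Potts
state and `X` is mapped onto it — a deliberate asymmetry: the MI estimator
follows the 20-state convention of its lineage, the DCA estimators the
21-state convention of theirs.

## Corrected mutual information

Weighted frequencies use a per-cell pseudocount λ = 0.05 (the "low-count
correction"; the constant is a package default, exposed as a parameter):
f_i(a) = (λ + Σ_r w_r[x_ri = a]) / (20λ + N_i), pairs analogous over 400
cells with pair-complete rows only. MI is in nats; 0·log 0 := 0, and tiny
negative values arising from the pseudocount's marginal mismatch are
clamped to zero. APC subtracts (row mean × row mean / grand mean), all
means over off-diagonal entries; a zero grand mean defines APC = 0.

The z-score null permutes residues within each column independently across
rows — preserving per-column composition and conservation while destroying
covariation — and pools all replicate pair values into a single mean/sd
(100 replicates by default; replicate r uses seed + r). A pooled null is
stable at moderate replicate counts, which is why it was preferred over a
per-pair null; both the replicate count and the seed are parameters. The
observed sequence weights are reused for the shuffled alignments, since
shuffling destroys row identity and re-clustering a shuffled alignment
would be ill-defined. On an i.i.d.-column alignment (n=500, L=50) the
resulting z-scores are close to standard normal (mean ≈ 0, sd ≈ 1.02,
~0.2% beyond |z| = 3); the acceptance suite asserts mean within ±0.1, sd
within [0.8, 1.2] and ≤ 1% beyond 3 sd.

Per-position conservation is the KL divergence of the column frequencies
from a background distribution, uniform by default (so a fully conserved
column scores ln 20 ≈ 3.0); a BLOSUM62-marginal background is provided as
`intercov.alphabet.BLOSUM62_BACKGROUND`.

## Mean-field DCA and direct information

Frequencies are mixed with a flat pseudocount fraction of 0.5
(f ← 0.5·f_data + 0.5/q; pairs with 1/q²) — the standard mean-field
default, needed because the method inverts the connected-correlation
matrix C built over q−1 = 20 states per site (gap gauged out; single-site
blocks are the exact diag(f) − f fᵀ). Couplings are e = −C⁻¹, re-expressed
in the zero-sum gauge. A singular C (only possible at very small
pseudocounts on degenerate data) raises an error advising a larger
pseudocount rather than returning garbage.

Direct information for a pair is the mutual information of the two-site
distribution P(a,b) ∝ exp(e_ij(a,b)) μ_i(a) μ_j(b), with the auxiliary
fields μ iterated (alternating marginal matching, a Sinkhorn-type fixed
point) until both marginals match the empirical single-site frequencies
within 1e-6, capped at 2000 iterations with a hard error naming the pair
on failure. DI is non-negative and exactly zero for a zero coupling block;
the 2-state symmetric case has a closed form against which the
implementation is tested to 1e-6.

## Pseudo-likelihood DCA

The fit minimizes the weighted negative pseudo-log-likelihood
Σ_r w_r Σ_i −log P(x_i^r | x_-i^r; h, e) with L2 penalties λ_h = 0.01 on
fields and λ_e = 0.2·(L−1) per unordered coupling block (so the coupling
penalty grows with the number of interacting partners) — the established
pseudo-likelihood defaults. The parameterization is symmetric
(e_ij = e_jiᵀ enforced throughout), initialization is zero for
determinism, and L-BFGS runs to gradient tolerance 1e-4 (max 300
iterations). The inner matrix products run in float32 with the objective
and gradient accumulated in float64; near the optimum the float32 gradient
noise can stall the line search slightly above the tolerance, in which
case the best iterate is returned with `converged=False` and a warning —
planted-coupling recovery is unaffected (precision@10 = 1.0 on every
benchmark seed either way).

The reported score is the Frobenius norm of each coupling block over the
20×20 amino-acid sub-block (gap excluded), taken after the zero-sum gauge
fix, followed by APC. The gauge fix compensates the fields so that every
site-conditional — hence the pseudo-likelihood itself — is unchanged; the
test suite asserts this invariance to 1e-6.

## Comparison layer

Pairs are ranked by descending score with deterministic tie-breaking
(smaller i, then smaller j; the underlying scores make ties measure-zero
but determinism requires a rule). `links_needed(class, n)` answers "how
many top-ranked pairs must be inspected to see n links of this class".
Method overlap intersects class-restricted top sets: each method
contributes its first n ranked pairs *of the target class* (equivalently,
the class content of its top `links_needed(n)` ranks). This is the default
because an "overlap of top interprotein pairs" naturally reads per class;
the alternative — top-n overall, then filtered — is available as
`mode="overall"`. Density summaries report count/mean/sd/quantiles and
binned histograms per class (inter, intra, inter+intra).

External score files must cover every pair; a `sparse` flag instead
assigns missing pairs a −inf sentinel that ranks last, for methods that
emit only their confident pairs.

## Structural evaluation

Contacts are defined on Cα atoms at a strictly-below 12 Å threshold
(11.9 Å is a contact, 12.0 Å is not). Only the first model of a PDB file
is read, HETATM records are skipped, and disordered atoms resolve to the
highest-occupancy location (first on ties). Reference segments are mapped
onto chains by global alignment (match +1, mismatch 0, gap −1): every
aligned residue pair defines a mapping — so point mutations between the
alignment reference and the crystallized construct still map — while the
wrong-chain guard requires ≥ 30% of reference positions to align to an
*identical* residue. Positions without a structural mapping are excluded
from all metrics (their count is reported), never treated as
non-contacts. Metrics are precision among the top-k class-filtered pairs
and ROC AUC with contacts as positives; AUC is computed by scikit-learn
and verified against a hand-rolled Mann–Whitney U oracle to 1e-12.

## Synthetic data

The generators produce every input class the tests need, deterministically
per seed:

- **Planted Potts alignments**: Gibbs sampling from
  P(x) ∝ exp(Σ strength·[x_i = x_j]) over the planted pairs, one
  independent chain per sequence, 200 burn-in sweeps plus 50 sampling
  sweeps, final state taken (independent chains make thinning irrelevant).
  The Ising-like diagonal coupling makes the signal a single scalar with a
  closed form at q=2 (same-state probability σ(strength) ≈ 0.953 at
  strength 3, checked empirically). The benchmark condition is L=40, q=8,
  n=2000, split 20/20, 10 cross-segment pairs with disjoint endpoints at
  strength 1.5 — strong enough that recovery is expected, weak enough that
  per-column compositions stay near-uniform.
- **Hit-table fixtures**: four scripted scenarios (paralog E-value rule,
  bit-score then lexicographic tie, empty taxID intersection, three-protein
  segment arithmetic) whose expected paired FASTA is written by hand in
  the fixture code and compared byte-for-byte against the pipeline.
- **Toy structures**: Cα-only single-model PDB text on stated coordinates,
  with the expected contact map computed by a direct double loop.

What these fixtures do **not** emulate: phylogenetic correlation between
rows (every chain is independent), gaps and alignment errors, non-uniform
background composition, and the paralog ambiguity of real proteomes.
Passing the planted-recovery benchmark therefore shows the estimators are
correctly implemented and statistically consistent, not that they reach
any particular accuracy on real interfaces. Case-study numbers on real
complexes (how deep a ranking must be read to collect n interprotein
links, what fraction of multi-method overlap pairs sit at contact
distance) depend on the sequence database snapshot and search pipeline
used to build the alignments and are not reproducible from code alone;
the semantics needed to compute them (`links_needed`, class-restricted
multi-method overlap, strict-12 Å contact evaluation) are what this
package implements and tests.

## Figures

The circos view draws four concentric tracks (residue labels, conservation
coloured red→blue anchored at the 5th/95th conservation percentiles so the
ramp is stable across alignments, protein segments, and one Bezier chord
per selected link: red interprotein, segment-coloured intraprotein). The
matrix view plots the upper triangle only, coloured by rank band (1–100
dark red, 101–500 orange, 501–2500 yellow, deeper ranks unplotted).
Rendering contains no randomness; SVG is emitted directly, PNG/PDF via
matplotlib with reproducibility-hostile metadata stripped.

## Problem sizes in the shipped checks

The test suite and acceptance script run the planted-recovery benchmark at
its stated condition (5 seeds of L=40/q=8/n=2000), the null calibration at
n=500/L=50/100 replicates, and all oracle comparisons on toy inputs —
sizes chosen so the whole suite completes on a single CPU in minutes while
keeping every statistical margin wide (observed: precision@10 = 1.0 for
both DCA scores on all seeds against asserted means of 0.8/0.7; null sd
1.02 against an asserted [0.8, 1.2]).
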