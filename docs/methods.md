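# Methods

## Problem and model

`coevcontact` predicts residue–residue contacts *between* two interacting
proteins from sequence coevolution, and converts those predictions into
distance restraints usable by structure-modeling programs. The central
object is a **paired alignment**: a multiple sequence alignment whose rows
are concatenated sequences `[x_1..x_p; x_{p+1}..x_{p+q}]` of the two
proteins taken from the same genome, with the boundary `p` separating the
two blocks.

The statistical model over paired sequences is a global Potts model
(pairwise Markov random field over 21 states — 20 amino acids plus gap):

    p(X) = (1/Z) exp( Σ_i v_i(X_i) + Σ_{i<j} w_ij(X_i, X_j) )

Fields `v_i` capture per-position amino-acid propensities; couplings
`w_ij` (21×21, symmetric under `(i,a,j,b) ↔ (j,b,i,a)`, zero for `i=j`)
capture covariation. Because the global normalizer `Z` is intractable,
parameters are estimated by maximizing the L2-regularized
**pseudo-likelihood**

    Σ_n λ_n Σ_i log P(x_i^n | x_{-i}^n)  −  λ_v‖v‖² − λ_w‖w‖²,

where each conditional is a 21-way softmax over
`v_i(a) + Σ_{j≠i} w_ij(a, x_j)`. The objective is smooth and strictly
convex for positive regularization, so the optimum is unique and
restart-independent; we verify both properties in tests. Optional
per-sequence weights `λ_n` (default: all 1) implement identity-based
down-weighting at 80%.

### Numerical implementation

All conditionals for all positions at once are a single matrix product of
the one-hot encoded alignment `(N, 21L)` against the coupling matrix
`(21L, 21L)`; the gradient is the mirrored product of the
(probability − observation) residuals. Couplings are parameterized by the
upper triangle (`i<j`) only and mirrored, so each unordered pair is one
parameter set; the analytic gradient accounts for both conditional
contexts a pair appears in and is verified against central finite
differences of an independent loop-based oracle at 1e−5 relative error.
Optimization uses L-BFGS-B (projected-gradient tolerance 1e−5, max 500
iterations by default, zero initialization). Non-convergence is flagged
on the result, not raised. A `dtype=float32` fit option performs the two
large matmuls in single precision — roughly twice as fast on one CPU —
and is used by the large benchmark fits, where only the coupling ranking
matters; accumulations and the returned parameters remain float64.

Regularization defaults follow the usual pseudo-likelihood contact
prediction convention: `λ_v = 0.01`, `λ_w = 0.01·(L−1)`, scaling the
coupling penalty with the number of neighbors each position has. Both are
configurable.

A consequence of the *joint* shared-coupling objective worth knowing:
alignments with zero covariation (e.g. identical rows) do **not** fit to
`w = 0`. A coupling on the observed letter pair raises two conditionals
per unit of penalty, so perfectly conserved columns carry substantial but
*uniform* couplings. This conservation background is precisely what the
average product correction removes, and the corrected scores vanish in
that situation (tested).

## Paired alignment construction

Individual family alignments are read from FASTA/A3M (lowercase insertion
states removed), mapped to query columns (columns where the query is
gapped are dropped; `colmap` records the 1-based query position of every
retained column), and validated over the 21-letter alphabet with
nonstandard letters (B, Z, X, U, O, J) mapped to gap.

Pairing exploits prokaryotic operon structure. For genes of two families
in one genome, Δgene = |Δ accession index| − 1 counts annotated genes
between them (serial accession indices as position proxy). Per genome the
minimum-Δ candidate pair is formed; the family pair is accepted when the
Δgene mode is < 20 and the accepted Δ set — the mode plus the 2nd/3rd
most common value when within 1 of it (annotation ambiguity) — covers
≥ 60% of co-occurring genomes. Rows are emitted only for genomes whose Δ
is in the accepted set. Decisions taken where the rule leaves freedom:

- mode ties break toward the smaller Δgene (favors tighter linkage,
  deterministic);
- one row per genome, from the minimum-Δ pair;
- the conservation denominator is genomes containing both families (the
  only computable reading when records exist only for family members).

The concatenated alignment is then column-filtered (drop columns with
strictly more than 75% gaps) and redundancy-filtered (greedy scan keeping
rows with ≤ 90% identity to all kept rows). Identity = matches over
columns where neither row is gapped, divided by the count of such columns.
Columns are filtered before rows so the identity calculation reflects the
positions the model will actually see.

## Scoring

1. **Raw strength** `s_ij` = RMS of the coupling matrix entries, by
   default over the 20×20 amino-acid block (gap couplings mostly reflect
   alignment artifacts; a switch includes them).
2. **Block APC**: `s_corr_ij = s_ij − ⟨s_ik⟩⟨s_kj⟩/⟨s_kl⟩` with
   averaging sets restricted per block — both positions in one protein:
   averages within that protein (excluding the diagonal); one in each:
   the i-average runs over the partner protein's positions, the j-average
   over the first protein's, the grand mean over the inter block. This
   normalizes each family's evolutionary rate separately, and cancels any
   rank-one inter block exactly (tested to 1e−10).
3. **Normalization**: `ncs_ij = s_corr_ij / mean(top 3L/2 s_corr)` with
   `L = p+q`; about 3L/2 true contacts are expected for a complex of
   length L, so ncs ≈ 1 marks contact-level coupling. The normalizer pool
   includes all pairs (intra and inter) by default.
4. **Calibrated probability**:
   `GremlinScore(x, N/L) = 1/(1+exp(−σ(x−μ)))`, `μ = m/(N/L+1) + c`,
   with constants m = 0.47, c = 0.96, σ = 9.77 fitted once on the
   bacterial 50S ribosome and shipped as given. For the complex's
   top-ranked pair `x = √ncs`; all other pairs use `x = √ncs` scaled by
   the top pair's score, so an unconvincing best coupling deflates the
   whole complex. Negative corrected strengths are kept for ranking but
   floored at 0 before the square root.

   The midpoint formula is typeset ambiguously in its source; we use the
   reciprocal reading `μ = m/(N/L+1)+c` because μ must *decrease* toward
   c as alignments deepen (deeper alignments need weaker couplings for
   the same confidence); the linear alternative is available behind
   `mu_form="linear"`. `N` is the post-filter row count (pass `N_eff`
   to use the effective count); the top-score anchor is chosen among
   inter pairs (`top_pool="all"` widens it).

The per-protein-pair interaction statistic `summed_pair_coupling` sums
inter ncs values ≥ 1.5 (the threshold separating interacting from
non-interacting protein pairs in large-scale screens).

## Restraints

Scored pairs become sigmoidal distance restraints
`weight/(1+exp(−slope(d−cutoff))) + intercept` with `weight ∝ ncs`
(constant 1.0 by default): near zero when satisfied, approaching
`weight + intercept` when violated. The top 3L/2 inter pairs are
restrained. Centroid mode places one restraint between Cβ atoms (Cα for
glycine) with residue-pair-specific cutoff/slope from an editable YAML
table (default 8 Å / 2 where unspecified — the historical per-pair table
is not redistributed here); full-atom mode emits one ambiguous restraint
per pair over all side-chain heavy-atom combinations (cutoff 5.5 Å,
slope 4), scored as the minimum over alternatives. Writers produce a
native TSV and Rosetta constraint lines
(`AtomPair … SCALARWEIGHTEDFUNC w SUMFUNC 2 SIGMOID cutoff slope
CONSTANTFUNC intercept`, `AmbiguousConstraint … END_AMBIGUOUS`), both
golden-file tested.

## Evaluation

"Within X Å" is read inclusively (≤) everywhere. Two proteins are in
contact in a structure when any cross-chain Cα pair is within 12 Å.
Interface residue contacts use the minimal side-chain heavy-atom distance
(< 5 Å), where the side chain is Cβ and beyond (Cα for glycine); missing
atoms yield missing distances, never zero. Fnat is the fraction of native
interface contacts preserved in a model. iRMSD superposes the model's
interface Cα atoms (reference residues with any cross-chain Cα within
12 Å — the residue set mirrors the contact rule, since no standard set is
mandated) onto the reference by least-squares (Kabsch) rotation; the
rotation is verified against SciPy's `align_vectors`. PDB parsing uses
gemmi: first model, altloc blank/A, HETATM and hydrogens ignored.

## Synthetic data

`sample_potts` draws paired alignments from a specified Potts model with
planted inter-protein couplings (diagonal state-matching pattern,
magnitude 0.5–2.0) and optional sparse random fields. Sampling runs one
independent Gibbs chain per output sequence (default 100 burn-in sweeps,
sweeping sites in order; only coupled neighbors enter each conditional).
Independent chains make the returned sequences exact independent draws —
no thinning needed — and the sampler matches the exactly enumerable
Boltzmann distribution on a 2-position, 2-state reduction (χ² p > 0.01 at
N = 20000, tested). Gaps and unused states are suppressed via strongly
negative fields, so synthetic alignments are gap-free unless requested.

`make_genomes` plants ortholog pairs at a fixed Δgene in a configurable
fraction of genomes, scatters the partner at random larger distances
elsewhere, and adds distant paralog decoys; truth records the planted
rows. `make_toy_structure` builds two idealized alanine-like chains
(4 Å spacing) with listed residue pairs at an exact Cβ–Cβ contact
distance and everything else beyond it, validating the realized geometry.

What the generators do *not* emulate: phylogenetic correlation between
sequences, indel processes, alignment errors, paralog sequence similarity
and real side-chain geometry. Passing tests therefore demonstrate the
correctness of the estimator and scoring algebra under the model's own
assumptions, not performance on real protein families.

## Benchmark problem sizes

Two bundled studies (`coevcontact.benchmarks`) size the synthetic
experiments to resolve their effects in minutes on one CPU:

- **Planted recovery**: complexes of 25+25 positions, 10 planted
  couplings of magnitude 1.0, 5000 sequences, 10 replicate seeds; success
  = all 10 planted pairs within the top 12 inter pairs by ncs. Fits run
  in float32 with a 60-iteration budget: the convex objective's ranking
  stabilizes well before full convergence, so longer fits only add time.
- **Calibration curve**: complexes of 20+20 positions at depths
  N/L ∈ {1, 2, 4}, 4 replicates each, planted coupling 2.0 (strong
  enough to be detectable at depth 1, so all bins are populated).
  Empirical precision per score bin must rise with the bin and track the
  score value (slope ≈ 1), reproducing the depth-dependence built into μ.

## Known limitations

- Scores are only as calibrated as the shipped 50S-derived constants;
  they are not refit, and desk-scale synthetic data probes the shape of
  the calibration, not its absolute accuracy on real complexes.
- The pairing rule assumes prokaryote-style operons and serially
  assigned accession indices; eukaryotic genomes are out of scope.
- The centroid restraint table defaults to a single (8 Å, 2) setting for
  all residue pairs until a user supplies their own table.
- The Potts fit is dense in `L`; memory grows as (21L)² and the
  practical single-CPU range is L ≲ 300 paired positions.
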