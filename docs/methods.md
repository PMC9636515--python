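# Methods

## Mutation classification

Somatic variants are read from MAF (tab-delimited, standard column
names, `Tumor_Sample_Barcode` or a caller-named sample column) or VCF
4.x (via pysam; multiallelic records are split, shared flanking bases
trimmed, and the internal convention anchors insertions on the base 5'
of the event and deletions on the first deleted base). Both formats are
treated as 1-based. Classification uses a reference FASTA (pyfaidx) or
an in-memory contig map with 1-based inclusive coordinates.

* **SBS-96**: trinucleotide context under the pyrimidine-strand
  convention; purine-reference mutations are reverse complemented.
  Records whose reference allele contradicts the genome raise a
  consistency error; an ambiguous (non-ACGT) flanking base skips the
  record, and skips are tallied in a classification report rather than
  guessed at, so catalogs are deterministic.
* **DBS-78**: a doublet event and its reverse complement form one
  strand-agnostic class. The 144 → 78 canonicalization map is built once
  by enumeration over the ten canonical reference doublets (for
  palindromic references the lexicographically smaller alt is kept),
  giving an auditable lookup table rather than ad hoc string logic.
* **ID-83**: COSMIC-style bins. 1 bp indels are binned by the pyrimidine
  identity of the base (A/G runs complemented to T/C) and homopolymer
  run length — for deletions the run includes the deleted base
  (displayed 1..5, 6+), for insertions it is the pre-existing run
  (0..4, 5+). Indels of ≥ 2 bp are binned by length (2, 3, 4, 5+) and
  tandem-repeat-unit count; deletions that are not part of a tandem
  repeat but share ≥ 1 bp of flanking homology (longest shared prefix
  with the 3' flank or suffix with the 5' flank) are microhomology
  deletions binned by homology length, with the repeat check taking
  precedence. The "5+" length class also holds homology lengths up to
  5+, giving 83 bins in total.

Catalog matrices keep the canonical category order for each scheme, and
the text reader restores permuted rows and rejects negative entries or
unknown label sets. Column sums equal the number of classified mutations
per sample by construction.

## De novo extraction

The model is `V = P S + E` with `P` column-stochastic and `S`
non-negative. One extraction run proceeds as:

1. **Random start**: uniform random `P` normalized to column sum 1;
   random exposure fractions scaled to each sample's mutation total.
2. **Bootstrap + refinement**: the catalog is resampled per sample with
   a Dirichlet-multinomial whose concentration equals the observed
   counts (zero categories stay zero; per-sample totals are preserved;
   the expected resampled column equals the original). `P` and `S` are
   vectorized column-wise into one solution vector and the penalized
   objective `½‖V−PS‖² + α Σ_{i≠j} PᵢᵀPⱼ + β ΣS` is minimized with
   L-BFGS-B under non-negativity bounds, capped at `init_iters`
   (default 20 000) iterations. The smoothed solution is projected back
   to the feasible set (clip to non-negative, P columns rescaled to sum
   1 with the scale absorbed into S) and is only accepted if it does not
   worsen the objective of the start. The optimizer itself is a design
   choice: any bounded descent method satisfies the contract.
3. **Consensus**: `inner_runs` (I ≥ 5, default 5) refined starts are
   computed on fresh bootstraps; the five with the smallest error
   against the original `V` pool their 5K signature columns, which are
   clustered into K groups by k-means++ (10 restarts) on L2-normalized
   columns — Euclidean k-means on unit vectors, i.e. cosine geometry.
   Consensus signatures are cluster means renormalized to sum 1;
   exposure rows follow their column's cluster assignment and are
   averaged with the same grouping, keeping each (P, S) pairing
   coherent.
4. **Multiplicative updates**: `P ← P∘(VSᵀ)⊘(PSSᵀ)`,
   `S ← S∘(PᵀV)⊘(PᵀPS+γ)` until the relative change of `E = ‖V−PS‖²`
   over a 10-iteration window falls below `tol` (default 1e-8) or
   `max_iters` (default 100 000). Denominators are floored at 1e-12
   (logged once). The returned `P` is column-stochastic with the scale
   absorbed into `S`, so `PS` is unchanged; with γ = 0 the error is
   non-increasing (classical multiplicative-update monotonicity, checked
   numerically in the tests).
5. **Solution space**: `outer_runs` (Î, default 20) independent full
   runs per candidate K. Per-K stability is the mean silhouette width of
   all pooled signature columns clustered into K groups under cosine
   distance; K = 1 is assigned silhouette 1 by convention (a single
   cluster has no dispersion evidence). Error mean and standard
   deviation are recorded per K.

**Penalty defaults.** α, β and γ control accelerated-convergence
behaviour; no reference values are fixed by the method, so all three
default to 0 (plain NMF) and are exposed in `NMFConfig`. This is the
most conservative choice: penalties only activate when a user opts in.

**Choosing K.** A candidate K is *stable* when its mean silhouette is at
least the threshold (default 0.9) and the error drop to K+1, normalized
by the mean error at the smallest K examined, is below `flat_fraction`
(default 0.05). The scree-style normalization is deliberate: dividing
each drop by the current K's error inflates gradients once the fit
reaches the noise floor and degenerates the rule into "largest K with a
decent silhouette". The largest K in the range has no K+1 evidence and
can only be returned through the flagged argmax-silhouette fallback. The
full diagnostic table (silhouette, error mean/std, normalized drops,
stability flags) is always returned so users can override.

**Determinism.** All randomness flows through one seeded generator;
identical configuration and seed reproduce the solution-space summary
bit for bit.

## Exposure refitting

For a fixed, column-stochastic `P`, exposures solve `V ≈ P S` by
iterating only the `S` update from a uniform start (column total / K).
The subproblem is convex in `S`, so any positive start reaches the same
fixed point; the iteration cap is kept configurable up to 10⁸ but the
relative-residual tolerance (1e-10, checked every 50 iterations)
terminates in practice within a few hundred iterations. Samples without
mutations receive zero exposures and are flagged. Exposures are
normalized per sample *after* convergence. Agreement with per-sample
non-negative least squares is part of the test suite. γ defaults to 0
for refitting; a positive γ shrinks exposures and is exposed as an
option.

Presence calls are inclusive: a signature is present in a sample when
its exposure fraction is **≥** 0.20 (the default threshold).

## Signature comparison

Cosine similarity on raw (non-negative) profiles; undefined for zero
vectors. Matching against a reference set reports the full similarity
matrix, every match at or above a display threshold (default 0.6), and
the best match per extracted signature with ties broken by reference
column order. An extracted signature is renamed after its best reference
match with a `*` suffix when the best cosine reaches the rename
threshold (default 0.8, below the weakest match the naming convention is
modelled on); the rest are labelled `New`, `New2`, … in order.

## Cumulative contribution abundance

Given `P` and `S`, the attribution probability of category m in tumor n
to signature s is `ρ_smn = P_ms S_sn / φ_mn` with `φ_mn = Σ_k P_mk S_kn`;
ρ is scale-invariant in each sample's exposures, and cells with
`φ = 0` carry ρ = 0 with an explicit undefined mask. Per-gene counts
`N_mgn` (the Γ tensor, built from gene-labelled records with
intersection semantics against the supplied gene list and an optional
non-silent filter) give impact factors `ρ_mgn = N_mgn / Σ_i N_min` and
the length-scaled `ρ'_mgn = (N_mgn/l_g) / Σ_i (N_min/l_i)`.

The contribution term is reconstructed as
`θ_sgmn = ρ_smn · ρ_mgn · w_mn`. Two weightings are exposed:
*count_weighted* (default) with `w_mn = Σ_g N_mgn / Σ_m Σ_g N_mgn`, under
which a sample's contributions total exactly 1 over signatures, genes
and categories (making per-sample quantities proper fractions and the
6% threshold dimensionally meaningful), and *plain* (`w = 1`). The
choice is recorded in `CCAResult.weighting`. Cohort abundances are
`α_sg = Σ_m Σ_n θ_sgmn` and `η_sg` likewise with ρ'; α is additive over
disjoint sample sets, and η collapses to α when all gene lengths are
equal. The per-sample gene CCA is the count-weighted mean attribution
`c(s,g,n) = Σ_m N_mgn ρ_smn / Σ_m N_mgn`, which sums to 1 over
signatures for every mutated gene; `flag_low_cca` marks `c < 0.06`
(strict) as "little effect".

**Association statistics.** For genes mutated in more than 5% of
samples (strict), each gene × signature pair gets (i) a two-sided
rank-sum test comparing per-sample signature contributions (exposure
fractions when supplied, otherwise the gene's per-sample CCA) between
mutant and wild-type samples, and (ii) a permutation test on the
difference in median per-sample CCA under mutation-status label
shuffling (default 10 000 draws) with add-one correction,
`p = (1 + #{|diff*| ≥ |diff|}) / (n_perm + 1)`. One shared set of label
permutations per gene serves all signatures. Benjamini–Hochberg
q-values are computed within each signature by default (a global option
exists). Pairs with an empty group are flagged rather than scored. A
companion Fisher exact test relates binary signature presence to
mutation status, flagging degenerate margins and infinite odds ratios.

Because a gene's CCA is zero exactly in samples where it is unmutated,
the permutation test detects *any* mutated gene against its dominant
signature to some degree; ranking therefore uses q first and the median
CCA difference as the effect-size tie-break. This mirrors how
volcano-style readouts of the statistic are interpreted.

**Image export.** For deep-learning-style downstream consumers, one
(sample, signature) gene-CCA vector is laid out row-major into the
smallest square grid holding all genes, zero-padded, with genes ordered
by agglomerative clustering of cohort α profiles (average linkage,
Euclidean — the linkage is a documented choice) unless an explicit
order is given. The grid-fill reading of the square layout is one of
two defensible interpretations; the explicit `gene_order` argument
covers the other.

## Synthetic data

`simulate_catalog` draws K sparse signatures (per-column Dirichlet with
concentration 0.1, redrawn until all pairwise cosines are below 0.3 —
"well-separated" by construction), log-normal per-sample mixing
fractions (σ = 0.5) scaled to a fixed per-sample mutation count, and
catalogs either as the rounded exact product or as per-sample
multinomial draws. The defaults (M = 96, N = 50, K = 3, 1000 mutations
per sample, multinomial noise) are the standing conditions for the
recovery analyses.

`simulate_maf_reference` writes one random contig per gene plus a MAF
whose substitutions sit at positions whose trinucleotide context (on
either strand) realizes a category drawn from the active signature;
missing contexts are injected into the sequence before the FASTA is
written, and a ±1 bp neighbourhood of every used site is locked so later
placements cannot disturb a recorded context — which is what makes the
catalog round trip exact. Per-sample signature activities are Dirichlet
draws around the cohort mix (concentration 10); per-gene preferences
re-weight or pin the signature choice so association recovery is
testable end to end. Indels come from a fixed set of engineered context
templates (homopolymers, tandem repeats, a microhomology construct)
appended after each gene body, covering every ID-83 bin family; spacers
and in-template guard bases stop run/repeat scans at template
boundaries. The generator serializes its intended truth (signatures,
per-sample signature counts, intended category counts per scheme)
beside the outputs.

What the generator does **not** emulate: real human genome composition
and replication timing, transcriptional strand asymmetries, clustered
mutations (kataegis), copy-number context, or clinically structured
covariates. Passing recovery tests on these fixtures therefore
demonstrates correctness of the algorithms under the stated generative
model, not performance on any particular tumor cohort.

## Problem sizes and numerical choices

The recovery analyses run at M = 96, N = 50, K ∈ {2, 3, 4} with 5 inner
and 10 outer runs — enough repetitions for stable silhouettes while one
full solution space completes in well under a minute on one CPU; the
association calibration uses 200 samples, 20 genes and 2000
permutations. Tolerances: signature/exposure normalization is enforced
to 1e-9; multiplicative updates stop at 1e-8 relative error change
(1e-10 for refitting); update denominators are floored at 1e-12;
L-BFGS-B refinement inherits scipy's default function tolerance under
the 20 000-iteration cap. Degenerate inputs are handled explicitly:
all-zero catalog columns pass through resampling unchanged with a
warning, zero-mutation samples get zero exposures and a flag, empty
k-means clusters are re-seeded from the farthest column (logged), and
ρ/impact denominators of zero yield masked zeros rather than NaNs.

## Known limitations

* The Step-2 refinement is a bounded quasi-Newton descent; the original
  description fixes only the vectorize-optimize-smooth-restore shape,
  so other descent methods would satisfy the same contracts with
  slightly different starts.
* Multiplicative updates have a slow convergence tail near exact
  factorizations; the refit path (convex in S) does not suffer from
  this.
* Silhouette-based K selection assumes the solution space was built
  with enough outer runs; with very few runs the silhouette is noisy
  and the fallback flag should be heeded.
* Transcriptional-strand-aware catalogs, genome annotation/effect
  prediction and reference-genome download management are out of scope;
  gene labels and silent/non-silent flags are taken from the input MAF.
* The association permutation test inherits the structural coupling
  between mutation status and nonzero CCA discussed above; effect sizes
  should be read alongside q-values.
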