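# sigcca

Mutational signature analysis for somatic variant data: catalog
construction (SBS-96 / DBS-78 / ID-83), de novo signature extraction by
consensus non-negative matrix factorization, exposure refitting against
fixed signature sets, and a gene-level **cumulative contribution
abundance (CCA)** model that quantifies how strongly each gene's
mutations are attributable to each signature — with permutation-based
gene–signature association statistics.

## Who it is for

Cancer-genomics analysts who have somatic mutations in MAF or VCF form,
a reference FASTA, and want to go from raw variants to (a) signature
profiles and per-tumor exposures and (b) statements like "mutations in
gene *g* are preferentially generated by signature *s*".

## The model

A mutation catalog `V` (M categories × N tumors) is factorized as
`V ≈ P S` with column-stochastic signatures `P` (M × K, `Σ_m P_mk = 1`)
and non-negative exposures `S` (K × N; per-sample fractions sum to 1).
De novo extraction runs in five stages per candidate K: random
column-normalized starts; refinement on a Dirichlet-multinomial bootstrap
of `V` by minimizing the penalized objective
`½‖V − PS‖² + α Σ_{i≠j} PᵢᵀPⱼ + β ΣS`; pooling the five lowest-error
refined starts and condensing them with k-means into consensus starting
matrices; multiplicative updates
`P ← P∘(VSᵀ)⊘(PSSᵀ)`, `S ← S∘(PᵀV)⊘(PᵀPS + γ)`; and a solution space of
repeated runs whose silhouette widths and error gradients drive the
choice of K. Refitting against a fixed `P` (e.g. a COSMIC release)
iterates only the `S` update and works down to a single tumor.

Given a fit, each category m in tumor n is attributed to signatures with
probability `ρ_smn = P_ms S_sn / Σ_k P_mk S_kn`. Per-gene counts `N_mgn`
define gene impact factors `ρ_mgn = N_mgn / Σ_i N_min`, and the
contribution terms `θ_sgmn = ρ_smn · ρ_mgn · w_mn` accumulate into the
cohort abundance `α_sg = Σ_m Σ_n θ_sgmn` (and a gene-length-normalized
variant `η_sg`). The per-sample gene CCA
`c(s,g,n) = Σ_m N_mgn ρ_smn / Σ_m N_mgn` is a proper fraction over
signatures for every mutated gene; genes with `c < 0.06` are flagged as
having little effect on a signature, and signatures with exposure
fraction ≥ 0.20 are called present in a sample. Gene–signature
association combines a two-sided rank-sum test on per-sample
contributions with a permutation test on the difference in median CCA
(Benjamini–Hochberg corrected per signature).

## Worked example

Simulate a truth-known catalog (50 tumors, 1000 mutations each, three
sparse signatures), extract signatures with automatic K selection, match
them back to the truth and refit exposures:

```python
import sigcca as sc

cat, truth = sc.simulate_catalog(M=96, N=50, K=3, mutations_per_sample=1000, seed=1)
config = sc.NMFConfig(seed=1, inner_runs=5, outer_runs=10, k_range=(2, 3, 4))
space = sc.build_solution_space(cat, config)
k, table, stable = sc.select_k(space)
print(table.round(4).to_string(index=False))
print(f"selected K = {k} (stable: {stable})")

best = space.best_run(k)
match = sc.match_to_reference(best.P, truth.P_true)
print(match.best[["best_match", "cosine", "assigned_name"]].to_string())

refit = sc.inverse_nmf(cat, best.P)
present = sc.presence_calls(refit.fractions)
print("signature presence counts (>=20% of a sample's mutations):",
      present.sum(axis=1).tolist())
```

Output:

```
 K  silhouette  error_mean  error_std  n_runs  error_drop_to_next  stable
 2      1.0000 192972.6827     0.0079      10              0.7844   False
 3      0.9983  41597.8114     0.9506      10              0.0271    True
 4      0.9314  36360.7439    80.2026      10                 NaN   False
selected K = 3 (stable: True)
          best_match    cosine assigned_name
extracted
Sig1        TrueSig2  0.983206     TrueSig2*
Sig2        TrueSig3  0.982579     TrueSig3*
Sig3        TrueSig1  0.988085     TrueSig1*
signature presence counts (>=20% of a sample's mutations): [34, 37, 32]
```

Reading the table: at K = 3 the ten independent runs reproduce the same
three signatures almost exactly (silhouette 0.998), the reconstruction
error has dropped to its floor, and going to K = 4 buys only a 2.7% of
the K = 2 error while run-to-run variability jumps (error std 0.95 →
80.2) — so K = 3 is the stable choice, and each extracted signature
matches its generating truth with cosine ≈ 0.98.

The same operations are exposed on the command line:

```
sigcca catalog  --maf muts.maf --fasta ref.fa --scheme sbs96 --out catalog.tsv
sigcca denovo   --catalog catalog.tsv --kmin 2 --kmax 5 --seed 1 --out-dir fit/
sigcca refit    --catalog catalog.tsv --signatures cosmic.tsv --out fractions.tsv
sigcca compare  --signatures fit/signatures.tsv --reference cosmic.tsv --out sim.tsv
sigcca cca      --maf muts.maf --fasta ref.fa --signatures fit/signatures.tsv \
                --exposures fit/exposures.tsv --genes genes.tsv --out-dir cca/
sigcca associate --cca-dir cca/ --status status.tsv --nperm 10000 --seed 1 --out assoc.tsv
sigcca simulate --kind maf --n-samples 20 --seed 1 --out-dir sim/
```

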