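# Methods

This note documents the models, defaults and numerical choices behind
`alkagerm`, and what the synthetic-data generator does and does not emulate.

## Germination traits

A 7-day assay records, per accession × condition × replicate, the number of
seeds newly germinated each day (N₀ = 20 sown, 3 replicates) and end-point
root/shoot lengths. Traits per assay:

- GR = C₇/N₀ and GE = C₃/N₀, with Cₜ the cumulative germinated count.
- MGT = Σ t·nₜ / Σ nₜ over new counts nₜ — undefined (missing, never
  clamped) when nothing germinated; clamping to 7 would silently distort the
  panel tail, where near-zero germinators genuinely occur.
- GI = (1/N₀)·Σₜ Cₜ/t. The 1/N₀ normalization is this package's reading of
  the classical cumulative-count index: without it the index scales with
  seed number, and with it the day-3-complete assay evaluates to
  Σ_{t=3..7} 1/t = 1.093, matching the scale of published control-condition
  maxima. This is the single most consequential interpretive choice in the
  trait module and is pinned by tests.
- VI = mean shoot length × GI; RL/SL are replicate means in cm.

Traits are computed per replicate and averaged within condition; ratio
traits divide the replicate-averaged stress value by the control value and
are missing when the control value is 0 (RGE when GEC = 0). Population-level
ratio-trait means are means of per-accession ratios, not ratios of means.
Relative damage is 100·(mean RMGT − 1) for MGT (a delay) and
100·(1 − mean ratio) otherwise.

Summaries use sample SD (n−1) and CV = SD/mean; correlations are pairwise-
complete Spearman ρ with tie-corrected ranks; subpopulation contrasts use
one-way ANOVA plus pooled and Welch t-tests for a stated pair.

## Mixed-model association scan

The model is y = Xb + u + e with u ~ N(0, σ²g K) and e ~ N(0, σ²e I), where
K is identity-by-state kinship K[i,j] = mean(1 − |dᵢ − dⱼ|/2) over shared
non-missing SNPs of an LD-pruned subset (windowed greedy pruning, 50 SNPs /
step 10 / r² > 0.1, dropping the higher-missingness member, ties to the
later position). X is an intercept plus the top 3 eigenvectors of the
double-centered kinship (signs fixed by making each vector's
largest-magnitude entry positive); PCs are computed per panel.

Variance components are estimated once per trait on the null model by
spectral REML: project out X, eigendecompose the projected kinship, profile
the restricted log-likelihood over log δ (δ = σ²e/σ²g) on a 121-point grid
over [−10, 10] and refine with bounded scalar minimization between the
neighbouring grid points; a boundary optimum is flagged (it legitimately
occurs when the generating model has no polygenic background). Each SNP is
then tested by GLS in the eigenbasis of K with weights 1/(λᵢ + δ) — the
variance components are not re-estimated per SNP (the EMMAX-class
approximation). Missing dosages are mean-imputed per SNP; monomorphic SNPs
are skipped and counted; the Wald t-test uses df = n − rank(X) − 1. With
K = I the procedure reduces exactly to OLS, which the tests verify to 1e-8.

Multiple testing uses a simpleM-style effective marker number: per
chromosome, in non-overlapping 200-SNP windows, the smallest number of top
eigenvalues of the SNP correlation matrix capturing ≥ 99.5 % of the trace,
summed genome-wide; the suggestive threshold is 1/N. QC filters are strict
inequalities (missing < 0.20, MAF > 0.05), re-applied after subsetting to a
subpopulation panel. λ_GC = median(χ²₁(p))/0.4549 summarizes inflation.

## Loci, candidate genes, LD blocks

Significant SNPs are clustered greedily: the lowest-p unassigned SNP seeds a
locus and absorbs unassigned significant SNPs within ±150 kb on its
chromosome, so spans never exceed 300 kb. Loci from different traits/panels
are unified when lead SNPs lie within 150 kb (a stated choice — one unified
locus may hold several leads). Intergenic SNPs are assigned to the next gene
in ascending genomic coordinates; a strand-aware alternative would be
equally defensible, but the coordinate rule is deterministic without
assuming annotation orientation conventions. Candidate genes are the union
of three criteria, with provenance: (1) significant SNP in a gene flagged
stress-related by the user-supplied annotation table (disabled with a
warning when the table is absent), (2) significant SNPs for strictly more
than three distinct traits (configurable; the wording is ambiguous between
≥ 3 and > 3, and the strict reading is the default), (3) per trait, the gene
of the minimum-p SNP when p < 0.05/N.

Pairwise LD uses haplotype frequencies directly (inbred panels: haplotype =
dosage/2, heterozygous calls masked): D = p_AB − p_A·p_B, D′ = D/D_max,
r² = D²/(p_A p_a p_B p_b). Blocks use the Gabriel confidence-interval idea:
a likelihood profile over |D′| ∈ [0, 1] (allele frequencies fixed at sample
values, 101-point grid) yields 90 % bounds; a pair is "strong LD" when the
bounds lie in [0.70, 0.98+], "recombinant" when the upper bound is below
0.90; a candidate span containing the anchor SNP is accepted when its
endpoint pair is strong and ≥ 95 % of informative pairs inside are strong,
longest span first, falling back to a single-SNP block. The parameters are
the Haploview-style defaults and are configurable.

## Gene-CDS-haplotypes, Duncan's test, pyramiding

Coding SNPs are mapped to codons strand-aware (minus-strand alleles
complemented, offsets in transcript orientation) and classified by
translating the reference and alternate codon; nonsense and start-loss
changes count as non-synonymous defining sites. Haplotype keys are the
allele vectors over a gene's non-synonymous CDS SNPs; accessions
heterozygous or missing at any defining SNP are excluded (counts logged) —
losses are small in inbred panels. Haplotypes with n ≥ 10 are labelled
Hap1… by descending frequency; smaller ones pool as "rare" and never enter
tests.

Duncan's multiple range test orders group means and compares means p steps
apart against R_p = q(α_p, p, df)·√(MSE/n_h), with α_p = 1 − (1−α)^(p−1),
exact `scipy.stats.studentized_range` quantiles (no table lookups), pooled
ANOVA MSE, and the harmonic mean group size n_h for unequal n. Step-down
protection is applied (differences inside a homogeneous wider range are not
declared), and the compact letter display is built by insert-and-absorb;
with zero residual variance, unequal means are all declared different. The
display is verified in the tests against an independent brute-force
re-derivation of the grouping.

The favorable haplotype of a gene is the retained haplotype with the highest
mean RGE (the ratio trait most sensitive to alkali stress; the metric is
configurable), ties broken by larger n then lower label index. Pyramiding
groups accessions by their favorable(+)/inferior(−) pattern across the top
candidate genes (default 3, by best p), drops patterns with n < 15, compares
group means by ANOVA with Fisher's-LSD letters (pooled MSE at α = 0.05), and
reports the rank correlation between favorable-haplotype count and group
mean. qPCR support is the 2^−ΔΔCt fold change.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a two-subspecies rice diversity
panel, not its biology:

- **Genotypes.** Ancestral frequencies ~ U(0.05, 0.95); subpopulation
  frequencies Balding–Nichols with fst = 0.3 (default); per subpopulation 16
  founder haplotypes; accessions copy founders in blocks of 150 kb,
  re-drawing the founder with probability 0.9 at block boundaries; fully
  inbred (dosages 0/2) with 2 % missingness. The Hudson FST estimator over
  the emitted SNPs recovers the fst parameter (founder resampling adds
  ≈ (1−fst)/16); LD within blocks comes from the finite founder pool.
- **Defaults** (desk scale): 400 accessions (0.65 Xian / 0.35 Geng), 12
  chromosomes × ~1,667 SNPs (20,000 total) with clustered positions (short
  within-cluster gaps ~60 bp, long between-cluster gaps ~4 kb), 40
  single-exon genes placed over SNP clusters, 1–3 causal genes. A full
  simulation plus scan runs in seconds on one CPU; problem sizes are chosen
  so the whole replicate loop of the acceptance suite stays at desk scale.
- **Gene models.** Each CDS is ATG-initiated, stop-terminated, free of
  internal stops, length divisible by 3, on either strand, with the
  reference base equal to every SNP's REF allele. Causal SNPs are placed at
  codon position 1 with codon context chosen so REF→ALT changes the amino
  acid (verified by whole-CDS translation), and at sites with MAF ≥ 0.15
  within *every* subpopulation so the planted effect remains identifiable
  after structure correction — mirroring real candidate haplotypes that
  segregate within panels.
- **Phenotypes.** Latent tolerance L = subpopulation shift (±0.5) + Σ
  effect·(dosage/2) + N(0, 1), standardized. Each viable seed (p = 0.95)
  germinates on day round(exp(N(log μ, 0.25))) with μ = 3.7 under control
  and max(1, 3.7 + 1.5 − 1.0·L) under stress; days > 7 count as
  non-germinated. The discretized log-normal was chosen because two
  parameters reproduce a plausible long right tail of germination times
  (MGT spanning ~3–7 days). Root/shoot lengths are constants plus noise
  under control and linear in L under stress.
- **Not emulated:** coalescent genealogies, recombination maps, selection,
  outcrossing, dominance, multi-exon genes, genotype errors beyond uniform
  missingness, or environment × genotype interaction. Passing tests
  therefore demonstrate that the pipeline recovers known signals under a
  clean additive-inbred architecture; they do not certify behaviour under
  real 3K-scale LD or phenotypic error structure, and real-data effective
  marker numbers (and hence 1/N thresholds) will differ from the desk-scale
  values printed here.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; conversion happens only at
the VCF/GFF3/FASTA boundary. Heterozygous calls are dosage 1 in association
but excluded from haplotype assignment. Kinship eigenvalues are clipped at
0 before weighting; the REML grid refinement keeps the grid point if the
local optimization does not improve on it. Ties in LD pruning drop the
later position; ties in favorable-haplotype calls prefer larger membership.
RNG streams are spawned per stage from a single master seed, so stages can
be rerun independently without shifting other stages' draws; identical
configs reproduce byte-identical outputs, and result tables embed a hash of
the analysis-relevant configuration (not file locations).
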