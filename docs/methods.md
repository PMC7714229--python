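# Methods

This note documents the statistical model, the simulation machinery, the
numerical choices, and the limits of what the package's tests demonstrate.

## GBLUP and REML

The prediction model is intercept-only GBLUP: y = μ1 + g + e with
g ~ MVN(0, σg²K), e ~ MVN(0, σe²I) and K = MMᵀ/p from the −1/0/1 marker
score matrix. Two deliberate modeling choices:

- **No marker centering.** K is built from the raw ±1/0 scores, not
  VanRaden-centered dosages. This matches the coding convention the package
  standardizes on throughout (major homozygote = +1) and keeps F1 GEBVs
  exactly mid-parental by linearity. Users used to VanRaden kinships should
  note that diagonal values sit in [0, 1] for inbred lines and that
  population structure loads strongly onto K's leading eigenvector.
- **Intercept only.** No subpopulation or other fixed effects; structure is
  absorbed by g through K.

REML is implemented by spectral profiling: K = U S Uᵀ is decomposed once;
for a candidate ratio λ = σe²/σg² the rotated model has diagonal covariance
σg²·diag(s + λ), so the GLS intercept, the profiled σ̂g² = RSS/(n−1), and
the restricted log-likelihood

    −½[(n−1)·log σ̂g² + Σ log(sᵢ + λ) + log Σ xᵢ²/(sᵢ + λ)]

are all O(n) per evaluation. The optimizer is a 61-point coarse scan over
log λ ∈ [log 1e−6, log 1e6] followed by bounded Brent (tolerance 1e−8) in
the winning cell; both bracket endpoints are evaluated as boundary
candidates and flagged when they win (e.g. noiseless phenotypes drive λ̂ to
the lower bound). The test suite checks this path against an independent
dense-grid evaluation of the restricted likelihood written via
`slogdet`/`solve` (a different code path), and against ridge-regression
BLUP with the matched marker penalty p·λ, which is algebraically the same
predictor.

Henderson's equations are solved in the equivalent shrinkage form: μ̂ is the
GLS intercept under V ∝ K + λI and ĝ = K(K + λI)⁻¹(y − μ̂1). For invertible
K this is exactly the bordered-system solution (asserted in tests); for
singular K (n > p, duplicate lines) it is the pseudoinverse extension, and
predictions K_bp·K⁻¹ĝ are computed as K_bp·(K + λI)⁻¹(y − μ̂1), which is
exact because the rows of K_bp = M_bp Mᵀ/p lie in the row space of M.
When a persisted fit is reloaded without its training residuals,
K⁻¹ĝ falls back to a Moore–Penrose pseudoinverse with relative tolerance
1e−10.

**Known bias.** Genomic ĥ² = σ̂g²/(σ̂g² + σ̂e²) is calibrated when phenotypes
follow the fitted model (mean ĥ² within ±0.08 of 0.5 at n = 300 in the
suite). When phenotypes come from the structured QTL generator below
(3 subpopulations, Fst 0.15), mean ĥ² runs ≈ +0.08 high: between-
subpopulation genetic variance loads onto the uncentered K and inflates the
genomic variance. That is a property of genomic heritability on structured
panels, not an estimator defect; it is why the calibration test simulates
from the model.

## D-score and subset search

The diversity of a size-n₀ subset is det(K₀), the determinant of the
principal submatrix of the *same* K the GBLUP fit uses, restricted to the
candidate rows. Determinants are evaluated with LAPACK (batched over
populations of candidate subsets); values below 1e−14 are clamped to 0 so
near-singular submatrices (near-duplicate lines) cannot return sign noise.
0 ≤ det(K₀) ≤ Π K₀ᵢᵢ (Hadamard) for PSD K, asserted as a property test.

The search is a genetic algorithm over index subsets: population 50,
200 generations, crossover 0.9 (uniform exchange of the two parents' free
members, repaired to size n₀), mutation 0.1 (swap one member with a random
non-member), elitism 2, tournament selection of size 2, 5 independent
restarts, with a restart stopped after 60 generations without improvement.
Forced members (the top-2 GEBV lines in GEBV-GD strategies) are excluded
from crossover/mutation and always present. After the GA a deterministic
exchange polish repeatedly applies the best improving single swap until a
local optimum. Correctness is defined by the enumeration oracle: on
12-choose-4 instances the GA + polish attains the exhaustive optimum on
≥ 95 of 100 seeds and never exceeds it (in practice the polish makes misses
rare). Exhaustive ties break toward the lexicographically smallest index
set; GEBV ties break by stable id order.

## Meiosis and advancement

Gametes are simulated per chromosome as a two-state Markov chain over map
order: the starting haplotype is uniform, and the source switches at each
adjacent interval with the Haldane fraction r = ½(1 − e^(−2X)) of the
interval's genetic distance (X in Morgans; .map files carry cM, converted
internally by X = ΔcM/100). Independent Bernoulli switches per interval
mean no crossover interference, consistent with Haldane's function.
Implementation detail: because the first SNP of each chromosome has switch
probability ½, a single cumulative parity over the whole concatenated SNP
axis is valid — the uniform restart at a chromosome head makes the carried
parity irrelevant — which lets whole populations be advanced with one
vectorized draw. cM positions for unanchored SNPs come from linear
interpolation between flanking anchors; ends are extrapolated from the
nearest two anchors and clamped at 0 cM with per-chromosome monotonization
(the anchor-based maps this emulates do not define behavior outside the
anchored range, so this is a documented package choice).

Advancement (per strategy and repetition): phase the selected parents
(residual heterozygous loci get random phase — founders are near-inbred so
this matters little), make one F1 per parent pair (exact for fully inbred
parents), then each generation self every retained individual
`progeny_per_selected` times, predict GEBVs of the entire pool with the
trained model, and keep the `n_selected` directed-best **globally across
families** — a deliberate departure from the within-family selection many
breeding simulators default to, matching a mass-selection reading of
truncation on the pooled population. The final generation is kept whole;
F10 individuals retain their residual heterozygosity (~0.2% of loci from an
F1 start) rather than being forcibly fixed. Genetic gain is defined as
GEBV-F10 − GEBV-P (signed; for minimized traits favorable gains are
negative), and the identity gain ≡ GEBV-F10 − GEBV-P holds exactly by
construction.

Seeding: repetition r of an evaluation uses root seed + r; every stochastic
stage in the repetition (GA seed, founder phasing, every gamete) draws from
that repetition's `numpy` Generator stream, so reruns are bit-identical. By
default the same repetition seeds are shared across strategies (a paired
design, so strategy contrasts are not inflated by Monte Carlo noise);
`paired_seeds=False` makes them independent. The LSD comparison is valid
either way.

## LSD comparison

Per-repetition outcomes are compared with Fisher's least significant
difference at α = 0.01, unprotected (no preliminary F-gate and no further
multiplicity correction, matching common reporting practice for strategy
tables): MSE is the pooled one-way-ANOVA residual mean square, and groups
differ when |mean difference| > t(1−α/2, N−k)·√(MSE(1/nᵢ + 1/nⱼ)). For two
groups this reduces exactly to the pooled two-sample t-test (asserted).
Compact letters are assigned greedily from the best-ranked group in the
trait's direction. Zero residual variance is handled as a degenerate case:
unequal means are significant, equal means are not.

## Synthetic data

`make_founders` emulates a structured inbred diversity panel: per-SNP
ancestral allele frequencies U(0.1, 0.9); per-subpopulation frequencies
Beta-perturbed around them with divergence parameter Fst (Balding–Nichols),
default 3 subpopulations at Fst 0.15; accessions near-inbred with
heterozygote rate 2% (within the 1–10% residual heterozygosity typical of
inbred panel data) and missing rate configurable (0–10% typical; panel
fixtures use 2%); bp positions uniform within chromosomes and cM
proportional to bp with monotone jitter. `make_phenotype` draws N(0, 1)
effects for n_qtl genotyped SNPs and rescales a decorrelated residual so
realized h² equals the target exactly. Defaults (200 accessions,
2 × 250 SNPs, 50 QTL, h² = 0.5) are the package's standing desk-scale study
conditions; test problem sizes (e.g. advancement to F6 with 20 × 60 = 1,200
per generation, 5 repetitions) are scaled-down versions of the full scheme
(F10, 45 × 60 = 2,700, 30 repetitions) chosen so the whole suite runs
comfortably on a laptop while preserving every structural property being
asserted.

What passing tests on this generator do **not** show: behavior under real
LD decay, genotyping error, unsequenced causal variants, dominance or
epistasis, genotype-by-environment interaction, or selection on phenotype
rather than GEBV. The generator exists to verify the machinery under the
model's own assumptions, plus controlled violations (structure,
heterozygosity, missingness).

## Quality control defaults

SNP filters: missing rate ≤ 0.05 and MAF ≥ 0.05, both computed on the raw
matrix and applied jointly; the MAF boundary itself is kept (removal uses
strict <). Thinning keeps one uniformly random SNP per zero-anchored
half-open bin (20,000 bp or 0.1 cM), per chromosome, deterministic given a
seed; zero-anchoring is a reproducibility choice since bin anchoring is
otherwise arbitrary. Missing genotypes are imputed as +1 (the major-allele
homozygote) *after* coding — the convention the QC pipeline (filter → thin
→ impute) assumes throughout.
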