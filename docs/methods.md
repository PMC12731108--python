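# Methods

## Model and procedure

`burdenscan` tests, gene by gene, whether rare deleterious germline
variants are over-represented in cases relative to controls.

**Sampling model.** After QC, qualifying variant observations are treated
as exchangeable: under the null each observation belongs to a case with
probability π = n_case/(n_case + n_control), independently. For a gene
with k case observations among m total, the burden p value is the
one-sided binomial upper tail P(X ≥ k | m, π). The burden unit is the
*variant observation per individual* (an individual carrying two
qualifying variants in a gene contributes two; a homozygous call
contributes one carried variant — at allele frequencies ≤ 1e-4
homozygotes are negligible). Dependence between observations of the same
carrier is ignored at this stage; the permutation correction below is
what restores validity.

**Enrichment measure.** The pooled-rate relative risk
RR = (k/n_case) / ((k+c)/(n_case+n_control)) compares the case rate with
the combined-cohort rate. It is finite with zero control carriers
(RR = (n_case+n_control)/n_case at c = 0), which matters for the extreme
genes a discovery scan surfaces.

**Qualifying variants.** Loss-of-function consequences (stop gain,
start/stop loss, frameshift, canonical splice-site disruption) qualify
outright; missense variants qualify when their deleteriousness rank score
(VEST4-style, in [0,1]) reaches a cutoff. The consequence→class mapping
is a shipped, editable YAML; unknown terms fall to `other` and are logged.
"Start-gain" (uAUG-creating) terms are deliberately unmapped: their
protein-level effect is ambiguous.

**Variable-threshold scan.** Score distributions differ across genes, so
the missense cutoff is chosen per gene: every observed missense score in
the gene (cases and controls pooled) is a candidate, and — when LoF
observations are in the mix — an additional sentinel cutoff above the
maximum score ("no missense qualifies") is included, since the LoF-only
configuration can dominate when the gene's missense observations are
control-heavy and the scan must dominate every fixed cutoff. The cutoff
minimizing the binomial p wins; ties go to the smallest (most inclusive)
cutoff. Counts are step functions of the cutoff, so this finite candidate
set is exhaustive.

**Permutation correction.** Case/control labels are shuffled across all
analysis samples; carrier structure and scores stay fixed, and the entire
statistic pipeline — including the threshold scan — is recomputed per
iteration. The corrected p value is (r+1)/(N+1), where r counts
permutations whose p value is **at most** the observed one. Ties count as
exceedances by default (`tie_policy="inclusive"`): on
single-variant-per-carrier genes this makes the corrected p converge to
the exact hypergeometric tail P(X ≥ k_obs) and keeps the estimate a valid
p value; a strict-inequality policy (`"strict"`) is available and logs
tie counts, but it is anti-conservative on discrete statistics (a gene
whose lone carrier is a case would receive the floor p). With zero
exceedances the corrected p equals the floor 1/(N+1) — 1.0e-7 at ten
million iterations. An early-exit option stops once r reaches a ceiling
(default 1000, relative error < ~7%), which is how genome-wide scans stay
cheap while headline genes can be run to full depth.

Implementation: per gene a carriers × cutoffs matrix of qualifying
observation counts is precomputed; column totals are label-invariant, so
each permutation only needs the case-carrier indicator vector (drawn
sequentially without replacement, vectorized across iterations) and a
table lookup of pretabulated binomial tails. Ten million iterations on a
four-carrier gene take well under a minute on one core.

**Analysis grid.** Six analyses per gene: three qualifying-class groups
(missense only, LoF only, combined) × two case subsets (confirmed
carcinomas only; carcinomas plus significant polyps). Under the
CRC-only subset, polyp cases are excluded from the analysis entirely —
never recycled as controls — and n_case shrinks accordingly. Genome-wide
thresholds are Bonferroni (α/n_genes) and a "borderline" level
(1/n_genes, one expected false positive per scan).

**Gene-set test.** Observations are pooled over a panel under one of
three rules: LoF (skipping LoF in oncogene-role genes, where loss is
presumed protective), missense with score ≥ 0.5, or their union. The
0.5 cutoff for the fixed-rule missense test follows the convention that
rank scores above one half indicate cancer-relevant impact.

**Replication mode.** A stricter QC profile (strict inequalities, GQ >
25, alt depth > 3, depth > 10, allele balance > 0.2) and ICD-10-derived
phenotypes: proximal colon cancer (C18.0, C18.2–C18.4), distal colon
cancer (C18.5–C18.7, C19, C20), controls = no C18–C20 code. Samples
matching both groups are flagged ambiguous and excluded from both;
colorectal codes outside both groups (e.g. C18.1, appendix) exclude a
sample from cases *and* controls. Candidate genes are evaluated twice:
at the discovery cohort's chosen cutoff, and with a fresh scan.

## QC and calibration

Genotype-level thresholds (GQ, depth, alt-allele depth, allele balance)
are minima in the discovery profile (pass at ≥) and strict in the
replication profile (>), matching the respective conventions; site-level
quality is always a strict cut on the scheme-matched score (VQSLOD for
VQSR-calibrated cohorts, QUAL otherwise); rarity requires AF ≤ 1e-4 in
both population databases, with a missing frequency treated as 0
(absent-from-database = unobserved, standard rare-variant practice; the
count of such variants is logged).

Calibration grid-searches user-supplied threshold settings, evaluating
the per-individual rate ratio of the two neutral classes. The objective
is |log(synonymous ratio)| subject to a two-sided binomial p > 0.05 on
*both* classes (two-sided because deviation in either direction signals a
batch effect); if no grid point is feasible, the unconstrained minimizer
is returned with a warning flag. Ties break toward stricter (higher)
site-quality cutoffs, then stricter allele balance, making the search
deterministic. The searched grid is a config input — the right quality
scales are cohort-specific, so no universal default grid is shipped.

Per-gene neutral-class binomial p values feed QQ diagnostics. QQ bands
are pointwise 95% order-statistic intervals: the k-th smallest of n
uniform p values is Beta(k, n−k+1), and the band is its 0.025/0.975
quantiles on the −log10 scale. Burden p values are discrete (hence
super-uniform); uniformity tests in the suite use the randomized
probability integral transform against the exact null CDF.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, at the
study's conditions: per-individual neutral counts are Poisson (synonymous
26.5/individual, matching the ~26.4–26.7 observed in cleaned exome
cohorts; in-frame indels 0.5/individual, a realistic rare-indel rate),
each neutral observation a private variant on a uniformly chosen gene.
Planted risk genes draw carriers per individual at cohort-specific rates
(headline-gene magnitudes are ~0.019 in cases vs ~2e-4 in controls), one
variant per carrier, LoF with configurable fraction, missense scores
Beta-distributed. Unplanted genes receive background deleterious variants
at 0.01 per gene per individual in both cohorts — a realistic rare
qualifying-variant rate for a sizeable gene, and enough observations per
gene (~20 at n=2,200) that the permutation statistic is fine-grained.
Case variants carry VQSLOD-like qualities (Normal(10,4)), control
variants QUAL-like (Normal(200,60)); a batch shift can displace one
cohort's site-quality/allele-balance distributions. A configurable
fraction of calls is sabotaged to fail exactly one genotype criterion.
All draws come from named substreams of the master seed, so identical
seeds give byte-identical tables and adding a stage never perturbs
another stage's randomness.

What the generator does **not** model: linkage disequilibrium,
relatedness, realistic site-frequency spectra, shared (non-private)
variants, sequencing reads, or annotation error. Passing tests therefore
demonstrate the statistics are correct under the stated sampling model —
not that real cohorts satisfy that model; the calibration machinery
exists precisely because real cohorts deviate.

## Numerical and design choices

* Binomial/hypergeometric/Beta tails come from scipy.stats; tails are
  tabulated per gene, so permutations are table lookups.
* The per-gene permutation stream is derived from the master seed and a
  CRC32 of the gene symbol (SeedSequence spawn key): results are
  independent of gene processing order and of which genes are run.
* Degenerate inputs: a gene with no qualifying-eligible observations
  reports p = 1 (flagged); RR is undefined (NaN, flagged) at k+c = 0;
  missense variants without a score can never qualify and are logged.
* Carrier-label indicators are drawn by sequential conditional
  probabilities (exact sampling without replacement), vectorized across
  permutations in batches of 2e5.
* Tables round-trip byte-identically: floats are written with repr and
  parsed with Python's exact float conversion (pandas' fast parser is
  not round-trip safe).
* Test problem sizes: the type-I check uses 50 genes × 100 replicates at
  200 vs 2,000 samples with 1,999 permutations; parameter recovery uses
  500 replicates at the full 212 vs 31,699 cohort sizes with 1e5
  permutations; oracle equivalence uses 20 instances at 1e6 iterations.
  These sizes give Monte-Carlo error comfortably inside the asserted
  tolerances while keeping the default suite fast.

## Known limitations

* The binomial model ignores within-carrier dependence; only the
  permutation-corrected p should be interpreted for inference.
* The inclusive-tie permutation p is mildly conservative on very sparse
  genes (heavy ties); the strict policy is anti-conservative — there is
  no exact-unbiased choice for a discrete statistic short of randomized
  tests.
* Covariate adjustment (ancestry PCs, age, sex) is out of scope: the
  design assumes ancestry-restricted, relatedness-pruned cohorts, with
  residual technical bias handled by the neutral-class calibration.
* Annotation (consequence terms, deleteriousness scores, population
  frequencies, protein positions) is consumed as input, never computed.
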