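# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `caprilink`. The package analyzes multi-country
livestock populations along two axes — pedigree connectedness via record
linkage, and genomic relatedness via LD, gametic-phase consistency,
inbreeding, PCA and admixture — and ships a synthetic generator that
provides all inputs plus ground truth.

## Identifier model and record linkage

Canonical IDs are 23 characters: breed (3) + registration country (3) +
sex (1) + core (16). The core is the 2-letter birth-country code followed
by the local number, the whole left-padded with zeros
(`ALPCHEF0000000FR5248383`). Because the registration-country letters
differ between the exporting and the importing record of the same animal,
all matching uses the (breed, sex, core) key, never the full string.

Linkage runs in four tiers of decreasing confidence:

1. **exact** — key equality, including keys built from the target's aliases;
2. **alias** — the target's ID (or an alias) equals a source record's alias;
3. **suffix** — the target core's digit string (taken after the
   birth-country letters, leading zeros preserved) is a trailing substring
   of exactly one source number. Minimum suffix length is 5 digits; ties
   yield no match. This recovers truncated re-registrations;
4. **fuzzy** — highest normalized Levenshtein similarity (0–100, via edit
   distance on the 16-character cores) among source IDs sharing the birth
   country. Scores at or above the threshold (default 90, i.e. at most one
   substitution in a 16-character core) are flagged `review` — never
   auto-accepted, because a one-digit difference may equally be a typo or a
   genuinely different animal; below threshold the record stays
   `unmatched`. Each source ID is consumed at most once per tier.

Connectedness tables count accepted matches as "found in local pedigree";
`review` and `unmatched` both count as missing. Foreign-parent tables scan
each national file for parents whose embedded birth country differs from
the registering country, counting direct progeny only. Proportions are
relative to the native pedigree of the matching breed (cell level), the
importing country's whole pedigree (row totals), or the breed-wide
pedigree (column totals).

## Inbreeding

Pedigree F uses the Meuwissen & Luo ancestor-list recursion: for animal
`i`, `A_ii = Σ_j L_j² D_j` over its ancestors, `D_j = 0.5 − 0.25(F_s +
F_d)` with unknown parents contributing `F = −1` (so founders have
`D = 1`), and `F_i = A_ii − 1`. Unknown parents are unrelated, non-inbred
founders: no unknown-parent groups or metafounders. The implementation is
O(n × ancestors) and is checked against the O(n²) tabular
relationship-matrix recursion to 1e−12.

Genomic F is the excess-homozygosity estimator on an LD-pruned panel:
`F = (O − E)/(L − E)` with `E = Σ_j (1 − 2p_j(1−p_j))` over the animal's
non-missing SNPs, using plug-in sample frequencies (no small-sample
correction; the choice is deliberate and documented rather than claimed to
match any particular tool's variant). The GRM diagonal minus one is
available as a secondary estimate (`grm_inbreeding`). Animals with fewer
than 100 informative pruned SNPs are flagged low-confidence. When the
frequencies come from a merged multi-population sample, F_het includes a
Wahlund component; the pipeline reports it side by side with pedigree F
per breed × country, plus the genomic-minus-pedigree difference of means.

## LD and gametic-phase consistency

`r² = D²/(p_A(1−p_A)p_B(1−p_B))`, `D = p_AB − p_A p_B`. With phased data
`p_AB` is counted directly over haplotypes; otherwise it is the ML
estimate from unphased genotypes via the standard two-locus EM, started at
linkage equilibrium and iterated to `|Δp_AB| < 1e−10` (max 1000
iterations). Only the double-heterozygote class is ambiguous, so the EM is
exact on tables without it. Decay curves use all within-chromosome pairs
in (0, 1 Mb], 50 classes of 20 kb, each labeled by the median realized
pair distance (midpoint for empty classes); pairs monomorphic in the
analyzed sample are excluded and counted.

Phase consistency between populations A and B is the Pearson correlation
of `sign(D)·√r²` over shared SNP pairs, per distance class
((0,1], (1,10], (10,20], (20,40], (40,60], (60,100], (100,200], (200,500],
(500,1000] kb). Sign comparability requires a shared allele orientation,
so both matrices are harmonized to a common reference allele per SNP
first; without this the statistic is meaningless across files. Classes
with fewer than 3 shared polymorphic pairs return NaN. The statistic is
symmetric in its arguments and exactly 1 in self-comparison.

## GRM, PCA, admixture

GRM is VanRaden's first method with frequencies from the analyzed sample;
missing calls are imputed to `2p_j` (zero contribution after centering)
and monomorphic SNPs are excluded. PCA is the eigendecomposition of G;
coordinates are eigenvectors scaled by √eigenvalue, variance shares are
eigenvalue/trace, and the sign convention (largest-magnitude loading
positive) makes coordinates reproducible.

The admixture model treats each genotype as binomial(2, θ_ij) with
`θ = QF`, Q row-stochastic ancestry proportions and F ancestral
frequencies. Fitting is plain EM — slower than accelerated quasi-Newton
schemes but monotone in the log-likelihood, which the tests assert. Q
starts from a symmetric Dirichlet(1) draw, F from sample frequencies with
seed-driven Gaussian noise (sd 0.1); F is clipped to [0.01, 0.99] and Q
renormalized each iteration; stopping at log-likelihood gain < 1e−4 or
2000 iterations. `choose_k` masks a random 10% of non-missing entries per
fold (default 5 folds), refits, and scores held-out entries by binomial
deviance; the selected k minimizes the mean deviance, ties going to the
smaller k. Cluster labels are only identifiable up to permutation;
`align_q_to_truth` greedily matches columns to a reference for scoring.

## Synthetic generator

The generator is the package's study design, not a fixture. Defaults:

* **Populations**: 2 breeds (ALP, SAA) × 4 countries (CAN, FRA, ITA, CHE),
  60 founders each, 5 discrete generations, 2 offspring per mating, 80%
  female offspring (dairy-herd sex ratio).
* **Divergence**: two-level Balding–Nichols. Ancestral frequencies uniform
  on [0.05, 0.95]; breed level F = 0.08; country level F = 0.05 (FRA),
  0.06 (ITA), 0.10 (CHE), 0.15 (CAN) — the transatlantic population most
  diverged, the two heavily connected European ones least. Draws are
  clipped to [0.01, 0.99].
* **Haplotypes**: per population, 20 ancestral templates drawn
  site-independently from its frequencies; founder haplotypes copy a
  template and switch to a random one between adjacent SNPs with
  probability `1 − exp(−2e−6 · d_bp)`. Template sharing produces r² that
  decays with distance; the finite template pool also adds a small extra
  layer of drift beyond the nominal F.
* **Map**: 2 chromosomes × 250 SNPs, 2.5 Mb each (10 kb spacing), uniform
  bp→Morgan at 1 cM/Mb, Haldane crossovers (Poisson count, uniform
  positions).
* **Exports**: sires only by default (live-animal flow in dairy goats is
  sire-dominated; dams can be enabled). Per-mating probabilities
  FRA→ITA 0.20, FRA→CHE 0.08, FRA→CAN 0.05, CHE→ITA 0.05 — France the
  universal exporter, Italy also importing from Switzerland, mirroring the
  unilateral flow pattern the analyses are meant to expose.
* **ID corruption** of imported registrations: truncation 0.10 (keep the
  last 5 digits), typo 0.05 (one substituted digit), alias 0.30 (local
  re-registration, true ID kept as alias), else clean. Local numbers are
  allocated with random strides of 100–150 so a single-digit typo almost
  never lands on a real number, and typos are retried against the source
  country's allocated numbers: a collision would be unresolvable for any
  linkage method and indistinguishable from a correct record.
* **Genotyping windows** (birth years, base year 1990, 3-year generations):
  FRA from 1993, CHE/CAN from 1996, ITA from 1999 — staggered national
  campaigns. Calls are masked missing i.i.d. at 0.02; the phased truth is
  retained unmasked.

What the generator does **not** emulate: coalescent-realistic haplotype
structure, mutation, selection, overlapping generations, non-random
mating within country, real chip manifests or TOP/BOT strand encoding
(allele labels are A/B and strand issues reduce to label swaps), and
pedigree sizes anywhere near national scale. Passing tests therefore
demonstrate correctness of the estimators and the qualitative behavior of
the pipeline under known structure — not calibration to any real
population's parameter values.

## Numerical and scale choices

* All randomness flows from one integer seed through named
  `np.random.default_rng` streams; identical spec + seed gives identical
  output, which the tests assert file-for-file on the report bundle.
* `qc_filter` order: sample call rate → SNP call rate → MAF, all strict
  `<` comparisons (boundary values retained); SNP statistics are computed
  after sample removal. The chain is idempotent except in the contrived
  case where removing a SNP pushes a sample just below the call-rate
  threshold on the second pass; at the generator's 2% missingness this
  does not occur.
* VIF pruning inverts the window correlation matrix; near-singular windows
  (pairwise |r| > 1 − 1e−10) drop the later member of the offending pair
  first. Retained sets are deterministic.
* The default pipeline (`RunConfig`) caps admixture EM at 300 iterations
  with tolerance 1e−2 and a k grid of 2..4 with 3 CV folds, keeping the
  full synthetic run around two minutes; the standalone functions default
  to the stricter 1e−4/2000 stopping rule. The acceptance script sizes its
  panels the same way (n = 200 / m = 2000 for Q recovery; 160 / 600 per
  seed for the k-selection study).
* Eigen-sign, duplicate-sample ties (first occurrence wins) and fuzzy-tie
  behavior (iteration order of the source pedigree) are all fixed and
  deterministic.

## Known limitations

* The EM estimate of `p_AB` from unphased genotypes carries information
  loss relative to phase counting: on gene-dropped data (~600 animals)
  about 96% of pairs agree within 0.02, with a mean |Δ| below 0.01 — an
  estimator property, not an implementation error.
* The suffix tier requires at least 5 surviving digits; registrations
  truncated harder than that fall through to fuzzy review or stay missing,
  as they would in practice.
* `F_het` on merged panels conflates individual inbreeding with
  population-level differentiation (Wahlund effect); interpret per-group
  means comparatively, not absolutely.
* Connectedness "missing in local pedigree" preserves unverified fuzzy
  candidates as missing rather than adjudicating them, matching a
  manual-review workflow.
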