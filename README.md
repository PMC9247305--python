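# caprilink

Cross-country pedigree linkage and population-structure analysis for dairy
goat breeding programs — with a synthetic multi-country data generator, so
the entire pipeline is testable without access to private national herd-book
and genotype data.

## The problem

Across-country genomic evaluation (e.g. single-step GBLUP pooling several
national training populations) is only worthwhile when the populations are
genetically connected. Assessing that connectedness from the data national
partners can actually share raises two distinct problems:

1. **Record linkage.** Countries register the same exported animal under
   different identifiers. With a standardized 23-character ID —
   breed (3) + registration country (3) + sex (1) + a 16-character core
   holding the 2-letter birth-country code and the zero-padded local number
   (an Alpine female with French ID 5248383 registered in Switzerland is
   `ALPCHEF0000000FR5248383`) — foreign animals can be traced back to their
   native pedigree. Reality intrudes: truncated numbers, typos, and local
   re-registrations with the original ID kept only as an alias.
2. **Genomic relatedness.** Even well-linked pedigrees say little about
   whether marker effects transfer between populations. That is measured
   from SNP genotypes: linkage disequilibrium decay, the consistency of the
   gametic phase between populations, inbreeding (pedigree vs genomic),
   PCA on the genomic relationship matrix, and model-based admixture.

## Statistics implemented

* **LD**: for two loci, `r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B))`,
  with `p_AB` counted from phase when known or estimated by the two-locus
  EM over the double-heterozygote ambiguity; decay summarized in 50 classes
  of 20 kb over (0, 1 Mb].
* **Gametic-phase consistency**: the Pearson correlation, between two
  populations, of `sign(D)·√r²` over shared SNP pairs, in nine distance
  classes from (0, 1] kb to (500, 1000] kb, after harmonizing the reference
  allele of every SNP.
* **Pedigree inbreeding** by the Meuwissen & Luo recursion (`F = A_ii − 1`);
  **genomic inbreeding** by excess homozygosity `F = (O − E)/(L − E)` on an
  LD-pruned panel (sliding-window VIF pruning, defaults 50/5/2).
* **GRM** (VanRaden method 1): `G = ZZ′ / 2Σp_j(1−p_j)`; **PCA** as its
  eigendecomposition with variance percentages from eigenvalue shares.
* **Admixture**: the k-cluster likelihood
  `Σ_ij [g_ij ln θ_ij + (2−g_ij) ln(1−θ_ij)]`, `θ = QF`, maximized by EM
  (monotone in the log-likelihood), with k chosen by entry-wise
  cross-validation deviance.
* **Record linkage** in four tiers: exact (breed, sex, core) key → alias →
  unique digit-suffix (for truncated registrations) → fuzzy normalized
  Levenshtein similarity. Fuzzy hits are never auto-accepted; they are
  flagged for review.

The synthetic generator produces two breeds × four countries under a
two-level Balding–Nichols divergence model, founder haplotypes as mosaics
of ancestral templates (LD decays with distance), gene dropping with
Haldane recombination, sire-dominated export flows with corrupted
re-registrations, and per-country genotyping windows — together with the
ground truth (match table, ancestry fractions, phased haplotypes) that the
tests score against.

## Worked example

```python
from caprilink import PopulationSpec, simulate_dataset, link_pedigrees, validate_pedigree
from caprilink.ld import phase_consistency

spec = PopulationSpec(seed=1)          # FRA exports to ITA/CHE/CAN by default
ds = simulate_dataset(spec)

fra, _ = validate_pedigree(ds.pedigrees["FRA"])
ita, _ = validate_pedigree(ds.pedigrees["ITA"])
matches = link_pedigrees(fra, ita)
print(sum(m.status == "accepted" for m in matches), "of", len(matches), "found")

prof = phase_consistency(ds.genotypes["FRA"], ds.genotypes["ITA"])
```

prints

```
French animals in the Italian pedigree: 40
found in the French pedigree:          38
  via exact  22
  via alias  13
  via suffix 3
  via fuzzy  2
phase consistency FRA-ITA (1,10] kb: 0.35
```

38 of the 40 French animals registered in Italy are traced back to the
French pedigree: 22 by the exact key, 13 through an alias, 3 by a unique
digit suffix (truncated registrations), 2 by fuzzy similarity (typos,
flagged for review). The FRA–ITA phase-consistency of 0.35 far exceeds the
FRA–CAN value under the same seed (≈0.05–0.15), reflecting the simulated
sire flow from France to Italy.

The full pipeline — QC, linkage, connectedness tables, inbreeding
comparison, LD/phase profiles, PCA, admixture — runs from one config:

```bash
caprilink run-all --out run1 --seed 1
```

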