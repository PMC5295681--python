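# clonedelim

Species delimitation and phylogeographic analysis for parthenogenetic
(clonal) organisms, built around the kind of multi-locus survey used for
widespread soil arthropods: a fast mitochondrial barcode (COI-like), a
slower nuclear protein-coding gene (H3-like) and a conserved ribosomal
fragment (28S-like), sampled across many locations, with deep cryptic
lineages and essentially clonal inheritance linking all loci.

For such data the usual sexual-species criteria do not apply, and the
package implements the two delimitation approaches used for asexuals,
plus the surrounding statistics:

- **Haplotype screening** — collapse identical sequences (literal
  identity, FaBox-style), translate coding loci (standard or invertebrate
  mitochondrial code), report lineage-diagnostic substitutions with
  synonymous/non-synonymous classification, mask codon positions.
- **Distances** — uncorrected p-distances (pairwise deletion),
  within/between group summaries, nucleotide diversity, JC69/K2P closed
  forms and pairwise-ML GTR+Γ(+I) correction with composite-likelihood
  model fitting.
- **GMYC** — single-threshold general mixed Yule-coalescent delimitation
  on an ultrametric tree.  With threshold T, interval i has branching rate
  `b_i = λ_Y k_i^{p_Y} + λ_C Σ_j (n_ij(n_ij−1))^{p_C}` and log-likelihood
  `Σ_i [ln b_i − b_i x_i]`; the threshold is profiled over all candidate
  ages and tested against a single-process null by a χ² LRT.
- **Birky's 4x rule** — for clades a,b compute `θ = π/(1−4π/3)` (larger of
  the two) and K = mean corrected between-clade distance; `K/θ > 4` ⇒
  different parthenogenetic species, `< 4` ⇒ same, `= 4` ⇒ explicit
  boundary verdict.  Overall grouping by connected components, with
  conflict flags for non-transitive verdicts.
- **AMOVA** — two-level analysis of molecular variance from pairwise
  difference counts with variance components, Fst and a permutation test
  (default 20,000 permutations).
- **Strict-clock dating** — UPGMA on corrected distances, node depths
  converted to ages at 0.0115 substitutions/site/my per lineage (2.3%/my
  pairwise, the standard arthropod COI rate).  A deliberate, labelled
  stand-in for MCMC dating, adequate for deep clean splits.
- **Synthetic data** — a coalescent simulator that reproduces the study
  design (5 Miocene lineages, 26 locations, 120 individuals, three linked
  loci on one genealogy) with known truth, so every stage is testable
  without downloads.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a default-design dataset and run the whole pipeline:

```bash
clonedelim simulate --seed 11 --out demo_data
clonedelim -v run-all demo_config.yaml
```

with `demo_config.yaml`:

```yaml
loci:
  - {name: COI, path: demo_data/COI.fasta, coding: true,
     genetic_code_id: invertebrate_mito}
  - {name: H3, path: demo_data/H3.fasta, coding: true,
     genetic_code_id: standard}
  - {name: "28S", path: demo_data/28S.fasta}
metadata: demo_data/metadata.tsv
outdir: demo_out
amova_permutations: 999
seed: 11
```

which prints

```
GMYC: 5 entities, LR=14.94, p=0.00187
4x rule: 5 species group(s)
reports in demo_out
```

The five GMYC entities are the five deep mitochondrial lineages; the
likelihood-ratio statistic compares the mixed Yule-coalescent fit against
a single-process null (χ², df = 3).  On this synthetic design the 4x rule
separates all five lineages (corrected between-clade K of 14–17% vs
within-clade θ below 0.5%, so K/θ ≫ 4 for every pair — e.g. E1 vs E2:
K = 0.136, θ = 0.0047, K/θ ≈ 29).  `demo_out/`
contains the full report bundle: haplotype tables, per-locus distance
matrices and group summaries, the GMYC entity list and fit report, the
4x-rule pair table (π, d, n, L, θ, K/θ with verdicts), the AMOVA table
(df, sums of squares, variance components, % variation, Fst, permutation
p), the dated chronogram in newick (ages in my) and a run manifest with
the seed and config hash.  Headline numbers for this run: between-lineage
COI p-distances 12.0–16.7%, within-location distances below 1% except at
the two mixed locations (the Denmark-like three-lineage location at
11.3%), 88.2% of COI molecular
variance among locations (Fst = 0.88, permutation p = 0.001), and the
deepest split dated at 8.0 mya.

The same stages are available as `clonedelim simulate | distances | gmyc |
fourx | amova | clock`, and as plain functions (`clonedelim.fit_gmyc`,
`clonedelim.four_x_all_pairs`, `clonedelim.amova_two_level`, ...).

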