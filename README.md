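# rilmap

Synthetic recombinant-inbred-line (RIL) cohorts and the genotyping-by-
sequencing (GBS) linkage-map analyses that characterise their genomic
constitution — built around the F6 perennial ryegrass (*Lolium perenne*)
RIL setting: a small cohort (41 lines) derived by single seed descent (SSD)
from one F1 between two inbred founders, genotyped with depth-dependent SNP
calls and dominant presence/absence variants (PAVs), and showing a marked
tendency for whole chromosomes to assort without recombining.

The package is for quantitative geneticists who want to reason about what a
small selfing-series cohort *should* look like — residual heterozygosity,
observable crossovers, non-recombinant chromosome fractions, segregation
distortion, LD structure — and to test the filtering and linkage rules used
on such data against a ground truth that real populations never provide.

## The models at the core

* **Meiosis**: a four-chromatid bivalent with one obligate chiasma per
  chromosome arm (position uniform; no interference), each chiasma
  exchanging one random chromatid of each homologue; a random chromatid is
  the gamete, so each chiasma transmits with probability 1/2 and a
  7-chromosome individual shows E = 14 junctions at F1. A Poisson
  alternative (chiasma rate 2 per Morgan per bivalent) makes cM Haldane map
  distance and reproduces the classical selfing junction density of 2 per
  Morgan at fixation. Per-chromosome suppression probability lets a
  bivalent resolve with no crossover — the phenomenological model of
  recombination suppression.
* **Selfing series**: per-locus heterozygosity halves each generation,
  E[het at F_g] = (1/2)^(g−1); the observed RIL recombination fraction
  relates to the per-meiosis fraction by R = 2r/(1+2r).
* **Observable crossovers**: B₀ = 14 at F1, halving each generation;
  cumulative expectation at generation G is Σ_{g≤G} B₀(1/2)^(g−1) —
  21.0 at F2 and 27.5 at F6 (27.5625 floored at one decimal).
* **Observation**: negative-binomial read depth, binomial allele sampling —
  a heterozygote at depth d is mis-called homozygous with probability
  2·(1/2)^d, the artifact that justifies scoring depth < 20 as missing;
  PAVs are emitted and called from proper-pair SAM records (flags 99/147,
  83/163), filtered to 1:1 ± 20% presence and mean pair depth ≥ 8.

## Worked example

```python
from rilmap import (GenomeModel, advance_ssd, truth_genotype_matrix,
                    analyze_constitution, cohort_summary,
                    expected_observable_crossovers)
from rilmap.observe import sample_marker_panel

genome = GenomeModel.ryegrass_default(suppression=0.4)
cohort = advance_ssd(41, 6, genome, rng_seed=2018)
panel = sample_marker_panel(genome, n_snp=1200, n_pav=0, rng_seed=7)
truth = truth_genotype_matrix(cohort.lines(6), panel.subset("SNP_codominant"))
s = cohort_summary(analyze_constitution(truth))
print(f"{s['denominator']} chromosome pairs, "
      f"{s['non_recombinant']} non-recombinant "
      f"({100 * s['non_recombinant_fraction']:.1f}%), "
      f"het {100 * s['average_heterozygosity']:.2f}%")
print("expected observable crossovers by F6:",
      expected_observable_crossovers(6, cumulative=True, floored=True))
```

prints

```
287 chromosome pairs, 82 non-recombinant (28.6%), het 3.56%
expected observable crossovers by F6: 27.5
```

i.e. at the calibrated suppression level close to a third of the 41 × 7 =
287 chromosome pairs are fixed intact founder haplotypes, residual
heterozygosity sits near the (1/2)^5 = 3.125% theory value, and the
closed-form cumulative observable-crossover expectation at F6 is 27.5.

## Analysis drivers

Numbered scripts under `analysis/` run the full narrative on the default
synthetic cohort (fixed seed), writing summary tables to `results/` and
bulky stage outputs (SAM, genotype matrices, pairwise tables) to
`scratch/pipeline/`:

1. `01_run_pipeline.py` — simulate → observe → QC → PAV-call → linkage →
   place → constitution → LD, with a manifest of parameter and output hashes
2. `02_qc_attrition.py` — marker counts through each filtering rule
3. `03_linkage_and_distortion.py` — grouping stability over a LOD 6–9 sweep;
   distorted-locus fractions per chromosome
4. `04_pav_placement.py` — placement accuracy against simulated truth
5. `05_constitution.py` — crossover counts vs the halving-model expectation;
   non-recombinant chromosome classes
6. `06_lineal_descent.py` — F2 → F6 coherence of homozygous regions
7. `07_ld_structure.py` — within- vs between-chromosome r², heat map
8. `08_suppression_sweep.py` — calibrating suppression to a ~31%
   non-recombinant cohort

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

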