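# Methods

`rilmap` simulates single-seed-descent (SSD) recombinant inbred line (RIL)
cohorts of perennial ryegrass and re-runs, on those synthetic cohorts, the
analyses used to characterise the genomic constitution of a small F6 RIL
population genotyped by sequencing (GBS): marker filtering and correction,
presence/absence variant (PAV) calling from alignments, two-point linkage
and LD, dominant-marker placement, and graphical-genotype crossover
accounting. This note records the models, the defaults and why, and what
the synthetic data does and does not establish.

## The meiosis model

A genome is a set of chromosomes with left/right arm lengths in cM; the
default is seven chromosomes with 75 cM arms (1050 cM total, the scale of a
ryegrass framework map). Meiosis is simulated on a four-chromatid bivalent:

* **Obligate-chiasma model** (default): exactly one chiasma per arm, its
  position uniform on the arm, no interference beyond the one-per-arm
  constraint. Each chiasma joins one randomly chosen chromatid of each
  homologue; a gamete is read off by walking a random chromatid axis left to
  right and hopping to the partner axis at every chiasma involving the
  current axis. Each chiasma is therefore transmitted to a sampled gamete
  with probability 1/2, giving one expected crossover junction per gamete
  chromosome — "one crossover per chromosome arm per meiosis" at the
  individual level (two gametes) means 14 junctions on a 7-chromosome
  genome. An earlier formulation that exchanged tails between the *evolving
  molecules* rather than the homologue axes was rejected: it under-produces
  junctions (3-strand doubles silently annihilate exchanges) and breaks the
  per-chiasma 50%-recombinant law.
* **Poisson model**: chiasma count per arm ~ Poisson(2 × arm length in
  Morgans), so the sampled gamete sees crossovers at the map rate and cM
  coordinates are Haldane map distance. Under this model the junction
  density of essentially-fixed lines approaches the classical selfing limit
  of 2 junctions per Morgan (map expansion factor 2), which the test suite
  verifies at F20.

**Recombination suppression** is phenomenological: per chromosome per
meiosis, with probability `suppression_prob` the bivalent resolves without
any crossover and the gamete receives an intact parental haplotype. Whether
suppression should act per meiosis or per lineage is not determined by the
data being emulated; per meiosis was chosen as the mechanistically simpler
reading. The pipeline default of 0.4 was calibrated with the sweep in
`analysis/08_suppression_sweep.py`: it brings the fraction of F6 chromosome
pairs fixed as intact parental haplotypes to ~31–34%, the regime reported
for the real F6 population (vs ~10% under the neutral model), and
correspondingly depresses observed recombination events per individual from
the theoretical 27.5 to the observed ~15–18.

**Viability selection** is available as per-locus fitness weights in (0, 1]
applied by rejection sampling at each selfing; it is off by default, so
segregation distortion in default cohorts is type-I error plus drift (which
is substantial when whole chromosomes assort without recombining in a
41-line cohort).

Selfing proceeds F1 → F6 by default with all intermediate generations
retained, enabling lineal F2-vs-F6 comparisons. Per-locus heterozygosity
halves each generation, (1/2)^(g−1), ≈3.1% at F6.

## The observation model

SNP calls: read depth per call is negative binomial (mean, dispersion);
true homozygotes are called correctly whenever depth ≥ 1; a true
heterozygote is called H only if both alleles appear among d binomial(d,
1/2) per-read draws, otherwise it collapses to the observed homozygote
(allele dropout — never the opposite homozygote). The miscall probability
2·(1/2)^d is what makes a depth-20 stringency rule effective: conditional
on d ≥ 20 the dropout probability is < 2×10⁻⁶. An extra independent
missing rate models non-depth dropout. Defaults for the pipeline's SNP
stream are mean 60, dispersion 10, missing rate 0.02 — the regime of SNPs
*retained* by a depth->20-supported framework map; at GBS-typical mean
depth 8 the stringency mask removes ~90% of calls and no usable framework
survives, which is demonstrated in tests but is not a useful default for
the downstream narrative.

PAV alignments: for each individual carrying the donor allele at a PAV
position, k read pairs (k negative binomial, default mean 8 — the
average-pair-depth scale the PAV filter assumes) are emitted as minimal
valid SAM records with proper-pair flags (99,147) or (83,163), both mates
at the marker's 1-based reference position, sample in the RG tag.
Configurable noise records carry flags 0/16/2048 and must be ignored by the
caller. The SAM is deliberately minimal (dummy CIGAR/SEQ/QUAL) but
standard-conforming; tests cross-check that pysam parses it to the same
records as the package's own lenient line-level reader (which exists
because the calling contract tolerates and counts malformed lines).

## Marker QC

Applied in a fixed order (running out of order raises a warning):

1. **Monomorphic**: drop markers with <2 distinct non-missing states; a
   strict mode requiring both A and B is available.
2. **Missingness**: drop markers with >35% missing over all individuals.
3. **Stringency**: calls with depth <20 scored missing (boundary: depth 20
   is kept).
4. **Singleton correction**: an isolated call whose flanking non-missing
   neighbours agree with each other and differ from it is set to missing —
   one pass, terminal calls never touched. On 1%-error cohorts this removes
   ≥90% of the spurious junctions that singletons would otherwise mimic.
5. **Binning**: same-chromosome markers whose call vectors match wherever
   both are non-missing (missing = wildcard) and that share ≥50% mutually
   genotyped individuals are merged by transitive closure; the least-missing
   member represents the bin. The 50% overlap floor prevents mostly-missing
   markers from bridging unrelated bins.

## Linkage, distortion and LD

Under `ril_self` coding heterozygotes are excluded pairwise and the
recombination fraction is the discordant fraction among A/B homozygote
pairs, capped at 0.5; LOD = n_c·log10(2(1−r̂)) + n_d·log10(2r̂) with r̂ the
uncapped MLE (this likelihood-ratio "linkage LOD" is used throughout, not
the independence LOD of some mapping suites; both are monotone in the same
two-point evidence). The observed RIL fraction relates to the per-meiosis
fraction by the selfing-series limit R = 2r/(1+2r), with the inverse
r = R/(2−2R) provided. Under `f2` coding the full 1:2:1 × 1:2:1 two-point
likelihood is maximised by EM over the 16 egg×sperm gamete combinations;
dominant markers are handled by enumerating the genotype classes compatible
with each observed symbol, which collapses the table automatically.

Grouping is single-linkage transitive closure on (LOD ≥ 6) ∧ (RF ≤ 0.35),
with the group count reported over a LOD 6–9 sweep. Segregation distortion
is a chi-square goodness of fit (1:1 on homozygote counts for RILs, df 1;
1:2:1 for F2 coding, df 2) at α = 0.05. LD is the squared Pearson
correlation of dosage (A=0, H=1, B=2), complete-case per pair; zero-variance
pairs are undefined.

PAV placement assigns each dominant marker to the framework bin with the
lowest RF subject to RF ≤ 0.2 and LOD ≥ 11, ties broken by highest LOD then
smallest map position (deterministic under marker permutation). The
thresholds are applied to the best hit. With 41 individuals LOD ≥ 11
effectively requires near-perfect co-segregation (n_c ≥ 37, n_d = 0), so
the placed fraction is governed by framework bin density; accuracy of what
does place is high (≥95% within 5 cM of truth at cohort size 200 with a
dense framework).

## Constitution analytics

Crossover counting follows a confirmation rule: scanning the non-missing
calls of a chromosome in map order, a state change counts as one
recombination event only if the new state persists for ≥3 consecutive
non-missing calls, counting the first call of the new block; unconfirmed
short runs are skipped and comparison resumes against the last confirmed
state; end-of-chromosome blocks get no exemption. Both interpretation
choices ("including the first call", end exemption) are exposed as flags.
A direct A↔B change counts as one event (block semantics), although two
junctions may underlie it. With `min_confirm=1` on error-free dense data
the scan equals the brute-force truth-segment/marker-intersection oracle
exactly; with injected 1% errors `min_confirm=3` keeps the count within 5%
of truth where raw counting inflates by >50%.

Chromosome classes follow graphical-genotype conventions: 1 = all
non-missing calls maternal homozygote, 2 = paternal, 0 = recombinant, with
chromosomes under 10 informative calls left unclassified (the floor is a
package choice to avoid labelling mostly-missing chromosomes). The cohort
denominator is individuals × chromosomes (41 × 7 = 287).

The observable-crossover expectation: B₀ crossovers are observable at F1
(default 14 = 7 chromosomes × 2 arms), the observable number halves each
generation as fixation masks new junctions, and the cumulative expectation
at generation G is Σ B₀(1/2)^(g−1), reported floored at one decimal
(21.0 at F2; 27.5625 → 27.5 at F6). An alternative published expectation
based on a 10-Morgan map (15.75/21) cannot be derived from its own stated
base and is deliberately not reproduced; the formula is parametrised in B₀
instead.

Lineal coherence marks any non-missing homozygous ancestor call that
changes state in the descendant as a violation (H may resolve anywhere);
error-free SSD transmission gives coherence exactly 1.

## Problem sizes and determinism

The default pipeline is study-scale: 41 lines, 7 chromosomes, 1200 SNPs +
120 PAVs (the 1200-SNP panel stands in for the larger raw panel at a size
whose binned framework still chains into linkage groups). Statistical
tests use the sizes at which their expectations are sharp: 2000 lines for
heterozygosity decay, 150 lines at F20 for junction density, 500 lines for
RF recovery, 200 lines for placement and grouping, 2000 null markers for
chi-square calibration. Every stochastic component takes a single integer
seed (one generator per run); the pipeline derives per-stage seeds by
hashing the master seed with the stage name, and a manifest records
parameters and output hashes so identical configurations reproduce
byte-identical outputs.

## What the synthetic cohorts do not show

The generator emulates map-space meiosis, depth-dependent genotyping error
and missingness, whole-chromosome non-recombination, and dominant PAV
observation. It does not model restriction-site fragment sampling, base
errors, barcode artefacts, reference/alignment error, physical coordinates,
NOR biology or self-incompatibility breakdown; suppression is a
phenomenological stand-in, and distortion under default settings is drift,
not selection. Passing tests therefore validate the *analysis rules and
estimators* under the stated statistical structure, not the sequencing
pipeline upstream of them, and agreement with published cohort-level
percentages is qualitative except where a quantity is closed-form.
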