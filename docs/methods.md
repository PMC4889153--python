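# Methods

This note records the statistical and algorithmic choices behind each module,
what the simulator does and does not model, and the known failure modes.

## Genetic model

A clonal hybrid `Pf` carries, at each nuclear locus, at most one allele from
each ancestral species `Pm` and `Pl`. The simulator represents a locus as a
quartet of lineages — `Pm`, the hybrid's `Pm`-derived allele (`Pf1`), the
hybrid's `Pl`-derived allele (`Pf2`), and `Pl` — sharing a random ancestral
coding sequence (default 2100 nt, 699 codons) partitioned into domains
(defaults NTD aa 2–430, DBD 431–530, LBD 531–699).

Planted variation:

- **Ancestral fixed differences** (per-domain counts): the `Pm` side
  (`Pm` = `Pf1`) differs from the `Pl` side (`Pf2` = `Pl`).
- **Lineage-private substitutions**: one named lineage differs from the other
  three.
- **In-frame indels**: codon-aligned insertions or deletions assigned to one
  or more lineages.

Each substitution is independently nonsynonymous with probability
`nonsyn_fraction` (default 0.5, Bernoulli per site); candidate codon changes
are drawn until the desired synonymy is achieved, so realized fractions
fluctuate binomially around the target. Frameshifts are out of scope: this
models coding loci of a viable hybrid, so indels are multiples of 3.

The **truth table** reports every planted site in ungapped `Pl` coordinates
with its polarity, coding effect, domain and code — the same representation
the detector emits, so recovery can be scored by exact row matching.

### Trio mode

With `single_allele_mode` set, the hybrid carries only the named ancestor's
allele. Classification then sees a trio (`Pm`, hybrid, `Pl`): the deviant
lineage at a site is called derived. A true ancestral difference is no longer
distinguishable from a `Pm`-private substitution (both look like "`Pm`
differs"), so trio truth tables project `ancestral` to `derived_in_Pm`.
This loss of resolution is inherent to the data, not to the implementation.

## Clone-read model

Clones are drawn uniformly from the hybrid's alleles; each read then receives
independent per-base errors (`base_error_rate`, default 1e-3, uniform over the
three alternative bases) and, with probability `chimera_rate`, is replaced by a
single-breakpoint template switch between the two alleles.

**Clone-set conditioning.** For heterozygous loci the sampler redraws the
allele assignment until each allele is carried by at least two non-chimeric
clones (at least one each when only 2–3 non-chimeric clones exist). This
mirrors how such loci are actually ascertained in practice: heterozygosity is
first established on direct chromatogram double peaks and each variant is
confirmed in multiple independent clones, so datasets in which one allele is
unsampled or seen once would be recognized and re-sequenced rather than
analyzed. Without the conditioning, a 12-clone binomial draw leaves one allele
with ≤1 clone in ~0.6% of loci, which is a data-collection failure rather than
an inference failure.

## Phasing

`infer_alleles` clusters identical reads, ranks clusters by support, and:

1. merges into the top cluster every cluster within `max_isolated_errors`
   (default 2) substitutions of it — these are sequencing-error satellites,
   not alleles. Consequently, true alleles closer than
   `max_isolated_errors + 1` variant sites are declared unresolvable up front.
2. takes the best remaining cluster as the second haplotype **only if** it has
   `min_support` (default 2) clones; otherwise its clones are excluded and a
   single-allele call is returned. A single clone cannot distinguish a rare
   allele from a doubly-errored read.
3. attaches every further cluster to the nearer haplotype if within
   `max_isolated_errors`; flags it as excluded if it is a mosaic of the two
   haplotypes (a chimera); and raises a `PhasingError` only for a
   well-supported cluster that is neither — that is evidence of a third allele
   and must stop the analysis rather than be silently dropped.

Per-haplotype consensus is column-majority over member clones, which removes
isolated errors.

**Chimera screening** (`detect_chimeras`) assigns each clone's state at every
informative site to haplotype A or B and classifies the clone as `clean_A`,
`clean_B`, `chimeric` (a single switch explains it and both segments have ≥2
informative sites), or `ambiguous`. A switch after the last informative site
is indistinguishable from a clean read and is called clean.

**Parental origin** is assigned by aligning each haplotype to both ancestral
references and taking the closer one; a heterozygous call whose two alleles
match the same ancestor cannot be canonically ordered and raises an error.

**Single-allele test**: if both alleles amplified evenly, clone counts are
binomial(n, ½); the test statistic is the 1-df χ² of the observed split
against (n/2, n/2), without continuity correction, with an upper-tail p-value.
For a 26:0 split this gives χ² = 26, P = 3.414E-07. The Monte-Carlo
comparison in the acceptance tests shows the asymptotic tail is within
simulation error of the exact binomial tail at n = 26 and n = 12 but not at
n = 6 (0.0143 vs 0.0312) — the asymptotic test should not be trusted below
about a dozen clones.

## Polymorphism classification

The four (or three) ungapped sequences are star-aligned to the `Pl` reference
with an affine-gap Needleman–Wunsch aligner (verified against exhaustive
enumeration for short sequences). Column patterns yield polarity:

- quartet: `ancestral` iff `Pm` = `Pf1` ≠ `Pf2` = `Pl`; `derived_in_X` iff
  lineage X alone differs; anything else is `complex`.
- trio: the deviant lineage is derived.

Coding effect comes from translating both states in frame. Codes follow
common reporting conventions: nonsynonymous `V87A`, synonymous `1227T>A`,
deletions `A528del` / `G173_V178del`, insertions `"247,AV,."` (after aa 247,
inserted residues, in-frame).

**Canonical event placement.** An indel in a repeat region — or an indel
flanked by a substitution — admits several equivalent representations of the
same pair of sequences. The detector reduces codon-level indels to the
leftmost codon-equivalent placement against the ungapped `Pl` reference, and
the simulator's truth table is produced by running this same representation
code on the true (noise-free) lineage sequences. Recovery scoring by exact
row comparison therefore never depends on alignment tie-breaking: a detected
table differs from the truth table only if a reconstructed sequence is
actually wrong.

**ASE markers**: ancestral substitutions (fixed `Pm`/`Pl` differences carried
heterozygously by the hybrid) are exported as SNP markers suitable for
allele-specific-expression assays.

## Expression analysis

- **Technical replicates**: CT values above the detection ceiling (default 35)
  are omitted per replicate; a sample is a non-detect only if all replicates
  are. Collapsing is by mean of the surviving replicates.
- **ΔΔCT**: ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the
  calibrator group's mean ΔCT; RQ = 2^(−ΔΔCT). The calibrator group's
  geometric-mean RQ is exactly 1 by construction.
- **Exact Wilcoxon rank-sum**: full enumeration of all group assignments for
  combined n ≤ 20, mid-ranks for ties, two-sided p as the probability of a
  rank sum at least as extreme as observed. Verified against an independent
  Mann–Whitney U-counting oracle for all small group sizes. Two-sided is the
  right default here because direction is not pre-specified per gene/tissue.
  With 4 vs 4 samples the smallest attainable p is 2/70 ≈ 0.029 — so under
  the significance marks `*` (0.01 ≤ p ≤ 0.05) and `**` (p < 0.01), a 4v4
  design can never produce `**`; that is a property of the exact test, not a
  bug. Benjamini–Hochberg adjusted p-values are reported alongside.
- **Reference-gene stability**: geNorm (mean pairwise SD of log2 expression
  ratios, iterative exclusion, pairwise-variation V(n/n+1)), BestKeeper
  (CT SD/CV and Pearson r against the geometric-mean CT index; a zero-variance
  gene has undefined r and is reported as such), NormFinder (model-based:
  sqrt of inter-group variance of gene-specific group effects plus averaged
  intra-group residual variance). NormFinder is the only one of the three that
  detects a group-confounded bias; geNorm and BestKeeper detect excess
  scatter.
- **Amplification efficiency**: from a dilution series, E = 10^(−1/slope) − 1;
  perfect doubling is slope −3.32/decade, E = 1. Values outside 0.9–1.1 are
  flagged.

## Measured performance and known failure modes

Over 100 simulation seeds × 3 presets, the full chain (simulate → phase →
assign origins → classify) recovers planted sites:

- base error 0: **100.0%** (3600/3600 site rows, 0 failed chains);
- base error 1e-3: **99.4%** (site-row accuracy over 3609 rows).

Residual misses at 1e-3 come from two sources: (a) an isolated error at a
planted site in enough clones to shift the column consensus, and (b) rarely, a
sequencing error adjacent to a planted indel that shifts the alignment in the
indel's neighbourhood and mis-places several sites at once. Both are
error-model artifacts that more clones would remove; neither occurs at error 0.

The simulator does **not** model: chromatograms or base-quality scores,
PCR-recombination hotspots (chimera breakpoints are uniform), non-uniform
error profiles, allele-specific amplification bias (the single-allele test's
null), RNA degradation, or inter-run qPCR batch effects.
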