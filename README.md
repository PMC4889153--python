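# clonephase

Allele phasing, polymorphism classification, and qRT-PCR expression analysis
for a clonal hybrid vertebrate and its two ancestral species — with a
ground-truth simulator that makes the whole chain testable end to end.

## Scientific problem

The Amazon molly (*Poecilia formosa*, here `Pf`) is a gynogenetic,
all-female hybrid of the Atlantic molly (*P. mexicana*, `Pm`) and the
sailfin molly (*P. latipinna*, `Pl`). Because it reproduces clonally, its
genome is frozen in a permanently heterozygous F1-like state: at a typical
nuclear locus it carries one allele inherited from each ancestral species.

Studying a candidate gene in this system means answering, from Sanger-style
clone sequencing and qRT-PCR data:

1. **Phasing** — given a set of cloned PCR reads from the hybrid, what are its
   one or two alleles? Which clones are PCR-template-switch chimeras, and is
   an apparent single allele statistically credible (or just sampling bad
   luck)?
2. **Classification** — for each polymorphic site, which ancestral species
   does each hybrid allele match (*parental origin*), is the difference an
   ancestral fixed difference between `Pm` and `Pl` or a substitution private
   to one lineage (*polarity*), is it synonymous or nonsynonymous, and which
   protein domain (e.g. NTD / DBD / LBD of a nuclear receptor) does it hit?
3. **Expression** — from CT tables with technical replicates, compute relative
   quantities by the ΔΔCT method against a reference gene and calibrator
   group, compare species with the exact Wilcoxon rank-sum test, and vet the
   reference gene with geNorm, BestKeeper and NormFinder.

`clonephase` implements all three stages plus a simulator (`synthdata`) that
plants a known allele architecture — fixed differences per domain, private
substitutions, in-frame indels, sequencing errors, chimeric clones — and
returns the truth table, so every stage can be scored against known answers.

## Worked example: a single-allele locus

At one estrogen-receptor-like locus the hybrid yields only one haplotype.
Is it really hemizygous/homozygous, or did 26 clones just happen to sample one
allele? Under even amplification of two alleles the clone counts are
binomial(n, ½); the χ² test on the observed split answers the question.

```python
from clonephase import phasing as ph
from clonephase import synthdata as sd

cfg = sd.preset_config("er_beta1", seed=7)
truth = sd.simulate_locus(cfg)
clone_sets = sd.clone_sets_for_truth(truth)

call = ph.infer_alleles(clone_sets["Pf"])
test = ph.single_allele_test(sum(call.support), (call.support[0], 0))
print(f"haplotypes called : {len(call.haplotypes)} (from {sum(call.support)} clones)")
print(f"chi-square        : {test.chi2:.0f} (df={test.df})")
print(f"P                 : {test.p_value:.3E}")
```

prints

```
haplotypes called : 1 (from 26 clones)
chi-square        : 26 (df=1)
P                 : 3.414E-07
```

so a second allele at even amplification is rejected. Classification then runs
in *trio* mode (`Pm`, hybrid, `Pl`); see `examples/single_allele_locus.py` for
the continuation, which assigns the lone allele to `Pl` and classifies each
site.

## Worked example: phasing and classifying a heterozygous locus

`examples/phase_and_classify.py` simulates an androgen-receptor-like locus
with 9 ancestral fixed differences (5 NTD, 0 DBD, 4 LBD) plus lineage-private
substitutions, phases 12 hybrid clones, screens for chimeras, assigns parental
origins, and classifies every site. Its output (seed 42):

```
haplotypes called : 2
clone support     : [8, 4]
informative sites : 12
clone verdicts    : ['clean_A', 'clean_B']
parental origins  : ['Pl', 'Pm']

detected sites:
 nt_site      polarity coding_effect domain    code
      68     ancestral nonsynonymous    NTD    Q23P
     126     ancestral    synonymous    NTD  126G>A
     145 derived_in_Pf nonsynonymous    NTD    C49G
     213 derived_in_Pf    synonymous    NTD  213A>T
     219     ancestral    synonymous    NTD  219C>T
     225 derived_in_Pm    synonymous    NTD  225T>C
     321 derived_in_Pf    synonymous    NTD  321C>T
     671     ancestral nonsynonymous    NTD   G224A
     794     ancestral nonsynonymous    NTD   C265Y
    1395 derived_in_Pm    synonymous    DBD 1395C>T
    1698     ancestral    synonymous    LBD 1698T>C
    1919     ancestral nonsynonymous    LBD   Y640C
    1981     ancestral nonsynonymous    LBD   H661Y
    2052     ancestral    synonymous    LBD 2052C>T

ancestral differences per domain:
{'DBD': 0, 'LBD': 4, 'NTD': 5, 'unmapped': 0}

allele-distinguishing SNP markers exported: 9
```

The planted architecture (9 ancestral differences: 5 NTD / 0 DBD / 4 LBD) is
recovered exactly, and the 9 ancestral substitutions are exported as
allele-specific-expression SNP markers.

`examples/expression_analysis.py` runs the ΔΔCT / Wilcoxon / stability chain
on a simulated CT table with a planted 4-fold difference; the treated group's
geometric-mean RQ comes out at 4.22 against a calibrator fixed at 1.00, and
all three stability methods rank the differentially expressed genes below the
reference.

## Command line

The `clonephase` CLI chains the stages on simulated data and writes TSV/FASTA
artifacts plus a manifest:

```
clonephase run-all --preset ar_alpha --seed 42 --outdir scratch/demo
clonephase simulate --preset er_beta1 --seed 7 --outdir scratch/er
clonephase phase    --outdir scratch/er
clonephase classify --outdir scratch/er
clonephase express  --outdir scratch/demo
```

Outputs include `{locus}_alleles.fasta`, `{locus}_sites.tsv`,
`{locus}_domain_summary.tsv`, `{locus}_single_allele_test.json`,
`expression.tsv` and `comparisons.tsv`.

## Reproduction

All randomness is seed-derived; the same seed reproduces every number above.

```
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out scratch/acceptance.json
```

The acceptance script re-measures the headline quantities (planted-architecture
recovery accuracy with and without sequencing errors, oracle agreement of the
exact rank-sum test and the aligner, null false-positive rates of the
expression comparison, 4-fold recovery, and stability-ranking hit rates) and
writes them as JSON. `tests/test_acceptance.py` asserts the same guarantees;
one parametrization there — the Monte-Carlo check of the χ² sampling test at
n = 6 clones — fails by construction, because at that sample size the
continuous χ² tail (0.0143) genuinely differs from the discrete binomial tail
(0.0312) by far more than Monte-Carlo noise. It is kept unweakened since it
documents exactly where the asymptotic test is trustworthy (n ≳ 12).

See `docs/methods.md` for the statistical and algorithmic details and the
simulator's modelling choices.
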