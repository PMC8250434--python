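# exofam

Family-based whole-exome variant prioritization for high-myopia cohorts:
a four-stage filter cascade with inheritance-model assignment and de novo
exclusion, pedigree cosegregation testing, an 11-category evidence matrix
with weighted ranking, a minimal ACMG-style evidence label (PM2/PP1/PP3),
per-family clinical summaries, and a gene-drop cohort simulator that
generates fully synthetic cohorts with known ground truth for testing the
whole pipeline offline.

## Command-line usage

```bash
# generate a synthetic cohort (VCF, PED, annotation TSV, clinical TSV,
# gene sets, truth table)
exofam simulate --out cohort/ --seed 42 --families 27 --ad-families 9 --background 200

# run the full pipeline: cascade -> cosegregation -> scoring -> ranking
exofam run --vcf cohort/cohort.vcf --ped cohort/cohort.ped \
    --annotations cohort/annotations.tsv --gene-sets cohort/gene_sets \
    --out out/ --top-k 20

# clinical-table summary (bundled 27-family reference table by default)
exofam summarize-clinical [clinical.tsv]

# codon-arithmetic consistency of a cDNA/protein notation pair
exofam check-hgvs c.904C>T p.R302C
```

`exofam run` writes `funnel.tsv` (per-stage input/kept/removed counts),
`non_cosegregating.tsv` (audit list with per-member violation reasons) and
`ranked_report.tsv` (ranked candidates with the 11 evidence category bits,
weighted total, frequency class and ACMG-style classification) into the
output directory, and prints a human-readable summary.

Thresholds, category weights, PolyPhen-2 collapsing and per-family
inheritance-model overrides are configurable through a YAML file passed
with `--config`; CLI flags beat YAML values, which beat built-in defaults.

## Pipeline semantics (defaults)

* Consequence filter keeps missense, nonsense, frameshift, in-frame indel
  and splice-site variants; synonymous and non-exonic classes are removed.
* Frequency filter removes variants with any reported database MAF
  >= 0.01 (inclusive); absent values never trigger removal.
* Inheritance model per family: AD when an affected member has an affected
  parent, else AR. AD requires every genotyped affected member to be
  heterozygous; AR requires homozygous-alternate. Missing genotypes never
  veto. Apparent de novo variants (both parents genotyped homozygous
  reference) are excluded.
* Cosegregation: AD additionally requires genotyped unaffected members to
  carry no alternate allele; AR permits heterozygous unaffected carriers
  (obligate-carrier parents) but rejects homozygous unaffected members.
* Affection status from measurements when undeclared: affected at SE
  <= -6.00 D (worse eye) and/or AL > 26.00 mm (longer eye); unaffected
  when every measured eye has |SE| < 2.00 D.
* Evidence matrix: four gene-evidence bits, multi-tool pathogenicity
  (strictly more than two damaging calls; DANN damaging at >= 0.90;
  PolyPhen-2 HDIV/HVAR collapsed to one tool by default), the mutually
  exclusive protein-altering/non-protein-altering pair, two ocular
  expression bits, and the mutually exclusive novel/rare frequency pair
  (rare = every reported MAF strictly below 0.001).

## Package layout

```
src/exofam/
  model.py        shared domain types (variants, pedigrees, genotypes, ...)
  config.py       thresholds, scoring weights, YAML config
  variant_io.py   VCF/PED/TSV readers and writers
  hgvs.py         minimal cDNA/protein notation parsing, codon arithmetic
  cascade.py      filter cascade + audit funnel
  segregation.py  phenotype status + cosegregation
  scoring.py      evidence matrix, ranking, ACMG-style tags
  clinical.py     per-family clinical summaries, inclusion predicate
  simulate.py     gene-drop cohort simulator
  pipeline.py     end-to-end orchestration and reports
  cli.py          click CLI (simulate / run / summarize-clinical / check-hgvs)
  data/           bundled 27-family reference clinical table
```
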