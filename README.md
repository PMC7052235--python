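# embryoscreen

Trio whole-genome screening of IVF embryos for clinically actionable
variants.

In preimplantation genetic testing (PGT), both parents are sequenced
from genomic DNA while each embryo is sequenced from a few biopsied
trophectoderm cells amplified by multiple displacement amplification
(MDA). Joint analysis of the three genomes classifies every embryo
allele as paternally transmitted, maternally transmitted or de novo,
but MDA introduces two artifact classes that dominate naive calling:
**allele dropout** (one haplotype's evidence vanishes over multi-megabase
stretches, mimicking loss of heterozygosity) and **false heterozygotes**
(spurious alt-supporting reads at a characteristic low variant allele
fraction). `embryoscreen` implements the analysis side of this workflow
for couples and embryos, from multi-sample VCF to a per-embryo clinical
screening report, together with a synthetic family generator that makes
every stage testable against known truth.

## What the screen does

**Inheritance-mode filters.** Six parallel filter sets per embryo:
dominant heterozygous, recessive homozygous, compound heterozygous,
X-linked, de novo, and a low-specificity high-sensitivity *failsafe*
(read depth > 1, no genotype-quality requirement, restricted to a
clinically actionable gene list) whose intentionally noisy output exists
for manual curation. Strict filters require embryo depth ≥ 10× and are
split into dbSNP-catalogued and novel subfilters. Every record carries
an ordered filter trail; nothing is silently discarded.

**Pathogenicity grading.** ClinVar pathogenic / likely-pathogenic
classes (with review stars) are used directly; variants ClinVar leaves
unresolved pass to a stacked prediction filter — retained only if

```
(#damaging verdicts among 6 predictors ≥ 2)  AND  MPC > 2  AND  CADD > 35
```

**De novo MDA gates.** False heterozygotes cluster at VAF 0.08–0.34
(peak ≈ 0.26), far below the 0.5 of a true germline heterozygote, so de
novo SNV candidates with VAF < 0.35 are rejected; novel-subfilter
candidates additionally need quality-by-depth QD > 12. Rejected
candidates are preserved with reasons for the curation path.

**LoH detection and dropout rescue.** Runs of > 100 informative sites
that are ≥ 95 % LoH-consistent are segmented per sample and trio-called:
embryo segments absent from both parents mark MDA dropout. Parental
pathogenic variants that the embryo data cannot confirm (low coverage,
uncalled, or inside a dropout segment) enter an *expected-but-missing*
ledger and are phased from the nearest informative flanking SNP on each
side of the missing region — agreeing flanks infer carrier or
non-carrier status; disagreeing flanks stay unresolved (no imputation,
no guessing).

**Binned CNV calling.** Depth tracks are averaged into 10 kb bins,
median-normalized per sample, and the embryo is scored against the
parents as controls: duplications need ratio > 2.0 with Z > 0,
deletions ratio < 0.5 with Z < 0, mean control depth > 5 and no QC flag
(high control variation, low control depth, low Z-score, within the
regional interquartile range). Calls are annotated against a
gene dosage-sensitivity table (haploinsufficiency / triplosensitivity),
trio-compared for inheritance, and recessive-evidence deletions are
cross-checked against trans pathogenic heterozygous SNVs/indels of the
same gene. Externally discovered SV intervals are ingested through the
same dosage and trio logic.

**Tandem repeats.** Repeat genotypes at a 17-locus disease panel are
classified against normal / premutation / pathogenic ranges and scored
for exact transmission concordance under the best one-allele-per-parent
assignment.

## Worked example

Simulate a family (two parents, three embryos; a dominant KRT10, a
recessive CFTR, a compound-het ABCA4, an X-linked GLA, a de novo ABL1
and a dropout-hidden PAH condition are planted, plus six CNVs ≥ 200 kb
and MDA artifacts), then screen it:

```
embryoscreen simulate --seed 1 --out demo/
embryoscreen run --config demo/config.yaml
```

The text report (`demo/report/report.txt`) begins:

```
== embryo EMBRYO1 (sex male) ==
  cnv_calls: 164
  compound_het_pairs: 1
  de_novo_rejected: 750
  de_novo_retained: 74
  dominant: 4
  dropout_suspects: 897
  expected_but_missing: 1
  failsafe: 135
  ...
  condition ABCA4: affected
  condition ABL1: affected
  condition CFTR: affected
  condition GLA: affected
  condition KRT10: affected
  condition PAH: undetermined
```

Reading this: the MDA gates rejected 750 de novo candidates (almost all
planted amplification artifacts in the 0.08–0.34 VAF band) and retained
74 — the planted true de novos, including the pathogenic ABL1 call.
The six planted conditions resolve to their true statuses; PAH, whose
causal variant was erased by a planted dropout region, lands in the
expected-but-missing ledger, and because this embryo carries a genuine
recombination inside that dropout the flanking-SNP rescue correctly
refuses to guess (`undetermined`). The 897 dropout suspects are
Mendelian-impossible homozygotes inside LoH segments — the expected MDA
signature, kept visible rather than deleted. Exit code 1 signals
findings left unresolved for curation.

## Package layout

| module | contents |
| --- | --- |
| `embryoscreen.trio_io` | data model, VCF/pedigree/annotation I/O, call-set concordance |
| `embryoscreen.inheritance` | transmission classifier and the six filter workflows |
| `embryoscreen.pathogenicity` | ClinVar ladder + stacked prediction filter |
| `embryoscreen.denovo` | VAF computation, VAF/QD gates, VAF histograms |
| `embryoscreen.loh` | LoH segmentation, trio LoH calls, missing-variant ledger, phase rescue |
| `embryoscreen.cnv` | 10 kb binned CNV calling, dosage annotation, trio inheritance, SV ingestion |
| `embryoscreen.repeats` | 17-locus tandem-repeat panel and transmission concordance |
| `embryoscreen.simulate` | synthetic family generator + ground-truth ledger |
| `embryoscreen.report` / `embryoscreen.cli` | orchestration, per-embryo reports, `embryoscreen` CLI |

See `docs/methods.md` for the models, parameter choices and known
limitations.
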