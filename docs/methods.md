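# Methods

## The screening model

Each family is analysed as a set of trios: father and mother genomes
(from genomic DNA) against each embryo genome (from MDA-amplified
trophectoderm biopsy DNA). For every biallelic site the embryo's
alternate allele is labelled by parental origin:

* **paternal / maternal** — exactly one called parent carries the allele;
* **ambiguous** — both parents carry it (or a parent genotype is
  missing), so single-site phasing is impossible;
* **de novo** — neither called parent carries it.

The classifier is a pure function of the three genotypes and is tested
against an exhaustive enumeration of all 27 diploid trio genotype
combinations.

Ambiguous-origin alleles are treated as transmitted for dominant and
recessive purposes; for compound-heterozygote pairing they leave phase
unresolved, so pairs involving an ambiguous hit go to a curation list
instead of being auto-called.

### Filter thresholds

| parameter | default | meaning |
| --- | --- | --- |
| `depth_min` | 10 reads | strict-filter embryo depth floor (">10×" read as ≥ 10) |
| `gq_min` | 20 | genotype-quality floor for strict filters |
| `failsafe_depth_min` | 2 reads | failsafe depth floor ("read depth > 1" read as ≥ 2) |
| `parent_confident_depth` | 20 reads | parent hom-ref at this depth makes an embryo hom-alt a Mendelian violation (dropout suspect) |
| VAF gate | 0.35 | de novo candidates with VAF < 0.35 rejected (inclusive at the boundary) |
| QD gate | 12 | novel-subfilter de novo candidates need QD > 12; missing QD fails |
| MPC / CADD | > 2 / > 35 | strict inequalities in the prediction stack |

The de novo workflow retains candidates regardless of pathogenicity
grade (the grade is carried on the candidate): de novo findings are
curated as a class, and the VAF/QD gates — not grade filtering — are
the specificity mechanism. The VAF gate is applied to all variant
classes; >1 bp deletions are known to run at higher artifact VAF, so
the variant class is recorded on every VAF point and the policy is
switchable in config.

Pseudoautosomal regions are treated as autosomal (hemizygosity logic is
invalid there); PAR coordinates are configurable and default to empty
for the synthetic genome. Embryo sex comes from the pedigree when
stated, otherwise it is inferred as male when the X heterozygosity
fraction is below 0.1 over at least 200 called X sites.

## LoH segmentation and dropout rescue

"Expected heterozygous" sites for the embryo are the obligate-het
universe: sites where the parents are opposite homozygotes, so any
transmission yields a heterozygote. For a parent sample the universe is
its own calls at family-polymorphic sites (runs of near-total
homozygosity then mark genomic LoH). Maximal runs with more than 100
informative sites and an LoH-consistent fraction ≥ 0.95 are emitted
(both the informative-site count and the LoH-consistent count are kept
on the segment). Embryo segments without ≥ 50 % reciprocal overlap with
a parental segment are labelled `embryo_only` — the MDA dropout
signature.

The expected-but-missing ledger covers every parental pathogenic or
predicted-pathogenic variant whose embryo call is absent, missing or
under 10 reads — and additionally variants whose adequately covered
call *lacks the expected allele while sitting inside an embryo-only LoH
segment*, where apparent homozygosity cannot be distinguished from
dropout. Without that extension, full-depth allele dropout (a clean
hom-ref call at 40×) could never reach the ledger.

Rescue phases the missing site against the nearest informative flanking
SNP on each side: carrier parent phased heterozygous, other parent
homozygous, embryo adequately covered. The transmitted carrier-parent
haplotype at a flank is the embryo genotype minus the other parent's
obligate contribution. Both flanks on the variant-bearing haplotype →
`carrier_inferred`; both on the other → `noncarrier_inferred`; one
usable flank or a disagreement → `unresolved`. The flank window
(default 1 Mb) opens from the LoH-segment *edges*, padded by 50 kb,
because sites inside (or immediately beside) the dropout carry the same
corruption that hid the variant. The method never guesses: a
recombination between the flanks produces disagreement, not a wrong
status. Its blind spot — two hidden recombinations inside the dropout
with agreeing flanks — is inherent to two-flank phasing and is shared
with the manual procedure it automates.

## Binned CNV calling

Per-sample depth tracks are averaged into 10 kb bins (apportioned by
overlap length) and normalized by each sample's autosomal median, so
ratios are scale-free. Male samples carry one X, so their
sex-chromosome values are doubled to the diploid-equivalent expectation
before scoring. The embryo bin ratio divides its normalized depth by
the mean of the two parents'; the Z-score is taken against the pooled
genome-wide distribution of the parents' normalized autosomal bin
depths — a per-bin Z across two controls would be degenerate at n = 2.

QC flags: `low_control_depth` (mean parental raw depth < 10, or absent
contig), `high_control_variation` (CV between the parents' normalized
depths > 0.5), `low_z_score` (|Z| < 1.5), `within_regional_iqr` (embryo
bin depth inside the interquartile range of the *controls'* normalized
depth over a ±50-bin window — the embryo's own window would self-mask
any CNV longer than about a quarter window). Because the parents serve
as each other's controls, a bin where one parent carries a genuine
called CNV would always trip the control-variation flag; bins
overlapping already-called parental CNVs are therefore exempt from that
flag (the parents are scored against each other first). Calls are
maximal runs of consecutive qualifying, unflagged bins — a single
flagged or non-qualifying bin splits the run — and must have mean
*parental* depth > 5 (the embryo's own depth is ~0 inside a homozygous
deletion, so the literal embryo reading would make deletions
uncallable).

With a diploid control, ratio > 2.0 and ratio < 0.5 confine discovery
to ≥ 2-copy gains and homozygous losses; a one-copy deletion sits at
ratio 0.5 and is intentionally not callable from depth alone. A
further consequence of parents-as-controls: an event shared by embryo
and a parent contaminates the control mean, which attenuates shared
*duplications* (copy 6 against a copy-6 parent scores ratio 1.5) —
shared deletions remain callable. The synthetic defaults therefore
plant inherited events as deletions. Small (one-bin) false calls are
expected and tolerated — the study design accepts a high CNV
false-positive rate and recovers specificity through dosage-sensitivity
annotation and trio comparison; what the caller guarantees on the
synthetic data is recovery of all planted events ≥ 200 kb and no false
call ≥ 100 kb.

## The synthetic family generator

The generator emulates the statistical structure the pipeline assumes,
on a miniature genome (four 10 Mb autosomes + a 10 Mb X) so a full
family simulates in seconds. Defaults are the study conditions:

| parameter | default | emulates |
| --- | --- | --- |
| `het_density` | 1/800 bp | candidate polymorphic site density (≈ 50 k family sites) |
| `mean_depth_parent` / `mean_depth_embryo` | 46× / 48× | the two library types' mean depths |
| `parent_nb_size` | 8.2 | NB dispersion giving ~96.4 % of 2 kb windows ≥ 20× |
| `embryo_nb_size`, `wave_sigma`, `wave_clip` | 3.4, 0.15, [0.6, 1.8] | MDA dispersion + bounded 100 kb amplification waves giving ~87.5 % ≥ 20× |
| `denovo_rate` | 74 | expected de novo SNVs per embryo genome |
| `artifact_het_rate` | 20 /Mb | MDA false-heterozygote density |
| `artifact_vaf_params` | Beta(10, 5) on [0.08, 0.34] | artifact VAF band with mode 0.26 |
| `tstv_target` | 2.081 | germline transition:transversion ratio |
| `crossover_rate` | 1.5 /chromosome | recombination |
| `dropout_regions`, `dropout_length` | 2, 2–3 Mb | MDA allele-dropout regions per embryo |
| `true_qd` / `artifact_qd` | N(20, 3) / N(6, 2.5) | QD at true vs artifact sites |

Design notes:

* **De novo rate is per genome, not per base.** The miniature genome
  carries the full-genome expected count (74) directly, so the de novo
  workflow runs at realistic candidate numbers and the count statistic
  is measured on the documented scale.
* **Artifact reads target the observed VAF distribution**: alt reads =
  round(VAF·DP) with VAF drawn from the scaled Beta. The reported band
  and peak describe the *observed* distribution, so the generator
  reproduces it directly rather than layering binomial resampling on a
  latent fraction.
* **Heterozygote depths are binomial at 0.5** (clipped to at least one
  read per allele, symmetric hence unbiased), which reproduces the
  parental heterozygote VAF centred at 0.5.
* **Substitution spectrum**: each SNV is a transition with probability
  Ts/(1+Ts) for the target ratio; no sequence-context model.
* **Depth**: negative-binomial per window; embryo windows additionally
  carry bounded lognormal 100 kb wave multipliers. The dispersion /
  wave split was fixed by calibrating to the two 20× coverage
  fractions; a pure Poisson cannot produce the embryo's coverage gap.
  The depth *track* does not additionally dip inside dropout regions
  (dropout is modelled at the genotype-evidence level; variant-site
  depths inside dropout are reduced ×0.55).
* **Forced transmission** of planted variants flips the
  whole-chromosome haplotype parity of the carrier parent, leaving the
  natural crossover structure untouched so flank phasing stays honest;
  at most one forced spec per parent per chromosome.
* **Planted CNVs** multiply window depth by copy/2 with a 3 % residual
  floor in homozygous losses (misaligned reads).
* Dropout regions are drawn on autosomes only; a planted variant marked
  `in_dropout` gets a forced region over it that drops the carrier
  parent's haplotype.
* Repeat-panel genotypes transmit exactly by default
  (`str_discordance_rate` 0) with parental alleles drawn from the
  normal range; the shipped pathogenic ranges are curated clinical
  defaults and user-overridable.

### What passing on synthetic data does and does not show

The generator reproduces the marginal statistics the pipeline's gates
key on (VAF distributions, QD separation, depth/coverage, Mendelian
structure, dropout-scale LoH) but not read-level reality: no alignment
artifacts with positional correlation, no sequence-context mutation
spectra, no population allele-frequency structure, no chimeric MDA
reads, and clean genotype calls outside the modelled artifact classes.
Passing tests demonstrate that the filters implement their definitions
and recover truth under the modelled artifact processes — not that the
thresholds are optimal for any particular sequencing platform.

## Numerical and policy choices

* Strict thresholds follow the printed inequalities literally: ">10×"
  → ≥ 10 reads; "read depth > 1" → ≥ 2 reads; VAF < 0.35 removed (so
  0.35 survives); QD > 12, MPC > 2, CADD > 35 strict; repeat
  `pathogenic_min` inclusive; LoH "> 100" variants strict.
* Missing evidence fails conservatively: missing QD fails the QD gate,
  missing MPC/CADD fails the prediction stack, missing predictor
  verdicts count as not-damaging, zero-depth VAF is undefined and is
  rejected with a reason.
* Multiallelic rows are decomposed (never dropped) with allele depths
  re-indexed; the "other" alternate allele becomes missing in the
  decomposed genotype rather than being recoded as reference. Indel
  keys are minimalised (shared suffix then prefix trimmed); full
  left-alignment against a reference sequence is out of scope.
* Concordance between call sets is computed over shared keys
  heterozygous in the first set, mirroring array-vs-sequencing
  validation; coordinate lift-over between platforms is external.
* Ties in STR assignment: the parent-to-allele assignment maximising
  the concordant count is reported; with equal scores the
  father-first assignment is kept (the count, which is what is
  assessed, is identical).

## Known limitations

* One family per run; no mosaicism modelling, no mitochondrial or
  imprinted inheritance, no polygenic risk.
* Binned depth cannot see one-copy deletions or shared duplications
  (see above); sub-10 kb CNVs are below the bin size by design.
* Phase rescue uses a single nearest informative SNP per side — no
  likelihood model, no recombination map; double recombination inside
  a dropout region can silently defeat it (it defeats any two-flank
  method).
* The failsafe filter is only as good as the supplied actionable gene
  list, which is a user input.
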