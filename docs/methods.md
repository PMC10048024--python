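# Methods

## Scope and data model

`equindel` operates downstream of read mapping and variant calling: its
inputs are per-sample (or merged) VCF 4.2 files with GT calls and
SnpEff-style `ANN` annotations, a registered-variant collection in VCF or
Ensembl-style GVF, and a two-column chromosome-length table. Only
insertion/deletion allele pairs are retained: a Ref/Alt pair is an INDEL
iff the alleles differ in length, so SNVs and equal-length substitutions
are dropped on read (calls referencing a dropped allele become missing).

A locus is a normalized `(chromosome, 1-based position, Ref, ordered
Alts)` tuple; loci with one alternative allele are diallelic, with two or
more multiallelic. Genotypes live in a loci × samples × 2 array of allele
indices with −1 for missing; allele pairs are unordered and stored sorted.

## Allele normalization and matching keys

Allele representations are made parsimonious (shared trailing base
trimmed while every allele keeps ≥ 1 base; shared leading bases trimmed
to a single anchor, advancing the position) and, when reference context
is available, left-aligned by the standard prepend-and-retrim loop.
Normalization is idempotent and never changes the size delta; a
brute-force search over all equivalent anchored representations on short
contexts is the test oracle.

Cross-format identity uses **anchor-free event keys**: a pure insertion
is `(ins, chrom, first-affected-position, inserted-bases)`, a deletion
`(del, chrom, first-deleted-position, deleted-bases)`. An anchored VCF
record and an anchor-free GVF line for the same event reduce to the same
key, which is what novelty lookup and the population database index on.
Length-changing substitutions keep their anchored form under a `cx` tag.

Integration merges per-sample records on the jointly normalized
`(chromosome, position, Ref)` anchor; distinct alternative alleles at one
anchor union into a multiallelic locus with Alts ordered by (length,
sequence). Records whose pairwise-normalized representations do not share
an anchor (e.g. deletion alleles of different spans) are kept as separate
loci rather than re-anchored — a deliberate simplification; see
Limitations. A sample without a record at a merged locus is **missing**
by default, because single-sample VCFs do not assert reference calls;
`assume_hom_ref=True` switches to homozygous-reference for gVCF-like
inputs. The choice matters for every "in all samples" predicate, so it is
an explicit flag rather than a silent default.

## Hard-filter engine

Thresholds (defaults in parentheses) follow the classic post-calling
criteria: depth DP < 10, quality QUAL < 30, a low-confidence band
30 ≤ QUAL < 50 yielding a LOWQUAL verdict, quality-by-depth QD < 1.5,
homopolymer run HRun > 5, strand bias SB > −0.1, and mapping-quality-zero
excess (MQ0 ≥ 4 and MQ0/DP > 0.1). The positional cluster rule flags a
locus when ≥ `cluster_size` (3, the conventional companion to a 10-bp
window) variants fall inside any `cluster_window`-bp (10) window
containing it — positions spanning ≤ window − 1 bp share a window. The
sliding-window implementation is O(n) and is tested against exhaustive
window enumeration.

Conventions: every criterion is evaluated independently and all violated
criteria are reported; LOWQUAL records are excluded from the retained set
by default (toggle available) since the band is listed among the filter
criteria without a stated action; missing INFO fields are recorded as
*not evaluated* rather than failed, because HRun/SB are
annotation-dependent and failing on absence would silently discard whole
call sets. Filtering is applied to the integrated matrix; on data where
each record carries the same INFO in per-sample and merged renderings
(as the generator emits) this is equivalent to per-sample filtering
followed by integration.

## Population statistics

Allele frequencies, MAF and the zygosity census are defined for diallelic
loci; multiallelic loci carry per-allele counts but no MAF and are
excluded from the AFS (they still count in totals, densities and
spacing). Missing genotypes leave every denominator. Densities are
count/length × 1000 (per kb); mean spacing is total length / total count
rounded half away from zero; reported percentages round half away from
zero at 1–2 decimals and MAFs at 5 decimals — fixed conventions chosen
for deterministic reports. X-chromosome genotypes are treated as diploid
for counting in pooled-sex panels; X summaries should be read with
hemizygosity in mind.

## Artifact signatures

The all-heterozygous MAF-0.5 signature requires, by default, a complete
call set: every sample called and heterozygous (which forces MAF 0.5).
Its probability under Hardy–Weinberg is (2pq)^n = 2^−n at MAF 0.5 —
about 3.9 × 10⁻³¹ for n = 101 — so flagged loci are treated as collapsed-
duplication mapping artifacts. Loci reaching MAF 0.5 through a mixture of
homozygotes are *not* flagged. The complementary signature is homozygous-
alternative in every sample (the reference assembly carries the minor or
erroneous allele). Suspect loci are clustered into regions by single
linkage with `max_gap` 100 kb and `min_loci` 10 (both exposed; the
defaults are reporting choices, not inferences). Suspects are always
reported, never auto-removed; the panel criteria and the population
database can exclude them explicitly.

## Novelty

Classification is exact match on normalized event keys; a multiallelic
locus is "registered" when **any** of its Ref/Alt pairs matches (registries
index alleles individually), with a strict all-allele mode available.
Reports stratify counts into ordinary diallelic, diallelic all-het
MAF-0.5 (quarantined because their variant status is doubtful), and
multiallelic loci; registry coverage is matched/total-registered.

## Annotation summaries

`ANN` entries parse as `Allele|Annotation|Impact|Gene_Name|Gene_ID|
Feature_Type|Feature_ID|Biotype`; each locus reduces to one primary
region class by the precedence exon > splice-site > 5′-UTR > 3′-UTR >
intron > upstream > downstream > lncRNA > pseudogene > intergenic, so
region tallies partition the locus set. A collapsed seven-row view folds
lncRNA/pseudogene into exon and splice-site into intron. Exonic coding
loci are frameshift iff |Δ| mod 3 ≠ 0; when the ANN label disagrees the
label wins and the discrepancy is reported (annotation context — e.g.
alleles spanning feature boundaries — can legitimately override the
length rule). The frequency-density matrix row-normalizes each category
across reference-allele-frequency bins to percentages summing to 100.

## Applications

Panel criteria: autosomal, diallelic, size delta in {−4,−3,−2,+2,+3,+4},
reference-allele frequency in [0.25, 0.75] with **inclusive** bounds
(frequency bounds symmetric, so Ref-frequency and MAF readings coincide),
excluding all-heterozygous loci. The selection equals the brute-force
conjunction of these predicates and is anti-monotone in every criterion.

The gene-editing screen takes a normalized query genotype: homozygous
alternative at an allele absent from both the population database and
the registered set → `SUSPECT_EDIT`; present but with population
frequency below `rare_threshold` (0.005, i.e. < 0.5%) →
`RARE_VARIANT_CAVEAT`, since rare natural variants complicate calls;
otherwise `KNOWN_VARIANT`; homozygous reference → `REFERENCE`.
Heterozygous carriers of an unseen allele also receive the caveat rather
than a suspect verdict — the screen criterion targets homozygous
("homologous") alternative-type variants. The database stores one entry
per normalized pair with alternative-allele frequency, call count and
flags; suspect-artifact entries can be masked so screening treats them as
absent while bookkeeping retains them.

## Synthetic-population generator

The generator emulates the *file-level* outputs of a resequencing
pipeline for a configurable population. Defaults describe a 101-sample
panel scaled to a 9-Mb toy genome (chromosomes 1, 2, 3, X and a 16,660-bp
mitochondrion):

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 101 | diploid individuals |
| `n_diallelic` / `n_multiallelic` | 4000 / 560 | ~12.3% multiallelic share |
| `afs_shape` | Beta(0.5, 2.0) | right-skewed true Alt-frequency law (rare-variant excess) |
| `size_distribution` | 1–4 bp ≈ 82% of mass, geometric tail to ±20; deletions 54% | Alt − Ref length |
| `n_artifact_allhet` / `n_all_alt_hom` | 50 / 20 | injected signature loci |
| `known_fraction` | 0.502 | loci copied into the registered set |
| `annotation_mix` | intergenic/intron-dominated genome shares | primary region classes |
| `missing_rate` | 0.0 | per-genotype no-call probability (ordinary diallelic loci) |

Genotypes at ordinary diallelic loci are Hardy–Weinberg draws (two
independent Bernoulli(p) alleles per sample) — the simplest model under
which the all-het signature is provably anomalous. Multiallelic loci are
modelled as microsatellite-like expanded-repeat insertions (one anchor,
alternative alleles appending 1..k copies of a 1–3-bp unit) with allele
frequencies from a symmetric Dirichlet; this keeps every per-sample
decomposition on a shared anchor so integration round-trips exactly, and
is a stand-in, not an inference about real repeat mutation. Injected
artifact loci are 0/1 in every sample, all-Alt loci 1/1; both always pass
the INFO filters (they emulate well-covered mismapped reads). Filter
violations are injected per criterion at configurable fractions with
violating values drawn inside the failing range; QUAL and LOWQUAL
injections are mutually exclusive. Positions sit on a jittered grid with
~30-bp minimum separation, so cluster-filter hits never arise by accident
(clustered layouts are constructed explicitly in tests). All randomness
flows from one seeded generator; identical config + seed yields
byte-identical files. A truth table records per-locus ground truth for
recovery tests.

What the generator does **not** emulate: linkage disequilibrium and
relatedness, read-level error processes, position-dependent coverage,
loci discovered only conditionally (all simulated loci are emitted even
if no sample realizes an alternative allele — deliberately, so
frequency-spectrum estimators can be validated without truncation bias),
deletion-type multiallelic sites, and genes spanning multiple loci
(each genic locus gets its own synthetic gene). Passing tests therefore
validate the statistical machinery and bookkeeping, not the upstream
calling pipeline or real-genome complexity.

## Problem sizes and verification

The test suite runs populations of 101 samples × ~3–5 × 10³ loci for
pipeline-level checks, 2 × 10⁴ loci for spectrum-shape recovery
(moment-based Beta estimates land within a few percent of truth;
the acceptance band is 10%), and 4 × 10³ loci against the exhaustive
cluster-window oracle — sizes chosen so the whole suite completes in well
under a minute while keeping sampling error far below the tested
tolerances. `scripts/acceptance.py` re-runs the full pipeline plus the
recovery experiment in a few seconds.

## Known limitations

* No re-anchoring during integration: deletion alleles of different
  spans at one site remain separate loci instead of one multiallelic
  record.
* Novelty and screening are exact-match; no fuzzy matching at
  microsatellite-like loci and no assembly liftover.
* X is counted as diploid regardless of sex; MT heteroplasmy is ignored.
* The strand-bias and quality fields are consumed as given — no
  re-derivation from reads, and no VQSR-style recalibration.
* Panel selection reports candidates only; exclusion-probability and
  typing-chemistry considerations are out of scope.
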