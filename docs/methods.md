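# Methods

## Problem setting

A catalog of germline pathogenic variants (PVs) in DNA damage repair (DDR)
genes is traced through three kinds of evidence: vertebrate species panels
(was the variant allele inherited through deep conservation?), ancient
human genomes (was it present thousands of years ago, and where?), and
modern cohorts split into Africans and non-Africans (did it arise before
or after the out-of-Africa dispersal?).  Founder-variant ages dated by
haplotype analysis and gene-level selection classes complete the picture.
All analyses key on opaque variant identifiers plus genomic coordinates
(1-based, forward strand, VCF convention); HGVS strings are carried as
labels and never parsed, because nothing downstream depends on their
internal structure.

## Damage-aware presence calling

Ancient DNA is fragmented and chemically damaged: post-mortem cytosine
deamination produces C→T miscalls near the 5′ ends of forward-oriented
reads and the mirrored G→A on reverse reads.  Rather than de-novo
genotyping, each catalogued site is interrogated in one individual's
pileup:

1. **QC cascade** — drop observations within `terminal_trim` bases of
   either read end (default 2, where deamination concentrates), below
   `min_base_qual` 20 or `min_map_qual` 30; collapse PCR duplicates (same
   fragment start, end, strand — ancient libraries carry no UMIs) keeping
   the highest base quality.
2. **Damage screen** — an alt read is deamination-consistent iff
   (ref C, alt T, + strand) or (ref G, alt A, − strand).  If *all* alt
   support is consistent and single-stranded, the site needs
   `min_alt_reads_damage` = 2 alt reads to be called present; otherwise
   `min_alt_reads` = 1 suffices.  Alt support on both strands always
   overrides the penalty, since one deamination lesion cannot produce
   both orientations.  Indels are never damage-flagged.
3. **Call** — present (thresholds met), absent (depth ≥ `min_depth` = 1
   and zero alt), else uncallable.  Zygosity: het if both alleles have
   ≥ `min_zyg_reads` = 2 reads, hom if only alt does, otherwise
   `present_unknown`.  Bases matching neither allele are tallied
   separately and excluded from both supports.

Thresholds are deliberately permissive — ancient genomes are low
coverage, and the goal is detecting known catalogued alleles, not
discovering new ones.  The caller is monotone: raising any quality
threshold can only remove support, never convert absent to present.

## Sharing analyses

The Venn partition splits the ancient cohort's PV set by membership in
the African and non-African carrier sets.  Headline fractions are
reported over the *shared* base (ancient PVs found in at least one
modern cohort), with the all-ancient base also emitted; both are
defensible and the choice is a reporting convention.  Per-gene load is
each gene's share of its cohort's nonredundant PV total; discordance is
the difference of shares.  Temporal profiles bin dated carriers in
half-open `[start, end)` BP intervals (default width 1,000 years,
oldest bin first); the default counting unit is the carrier-occurrence
(one per individual × carried PV), with a per-individual mode available.
Undated carriers are excluded from bins and reported separately in the
same units.  Pathway counts are many-to-many: a gene may sit in several
repair pathways, so pathway totals legitimately exceed the nonredundant
variant count.

## Rarefaction

PV discovery grows with cohort size, so raw sharing proportions from
cohorts of very different size are incomparable.  For each subgroup size
n and replicate, n individuals are drawn without replacement, their
carried PVs pooled, and the proportion of that discovered set present in
ancient genomes recorded; per-size medians and 5th/95th percentiles
summarize the 1,000-replicate distribution (replicates discovering zero
PVs are excluded and counted).  The default denominator is the
subsample's own discovery, matching the procedure of drawing subgroups
and then identifying PVs in each; dividing by the full cohort's PV count
is available behind a flag.  Default size grids are log-spaced between
1,000 (or the cohort permitting) and the smaller cohort's size.
Randomness is counter-based: each (size, replicate) cell derives its own
`SeedSequence` stream from the root seed, so results are bitwise
reproducible and independent of execution order.

## Cross-species projection

A species shares a PV when its observed allele at the orthologous
position equals the human alternate allele (nucleotide mode; a protein
mode comparing the species residue to the human mutant residue parsed
from simple HGVS p. substitutions is available, since allele-level and
residue-level conservation are both used in practice).  Missing orthology
scores not-shared but is tracked separately, keeping absence-of-data
distinct from presence-of-reference.  The nearest shared clade is the
least-diverged clade containing any sharing species, under a configurable
clade order (default: Fish, Sarcopterygii, Aves, Mammalia, Afrotheria,
Laurasiatheria, Euarchontoglires, Primate, most distal first).

## Founder ages and selection bootstrap

Published founder ages arrive as points ("8,675"), older–younger ranges
("1,500-750"), or bounds (">250", "<200"), all years BP; en-dashes and
thousands separators are normalized before parsing.  The representative
age used for ordering and thresholding is the older bound of a range and
the stated value of a bound — a conservative "no younger than written"
reading; midpoints are exposed for summary statistics.  A
literature-curated table of haplotype-dated DDR founder PVs ships with
the package.

The selection test transforms per-gene PV counts by log2(count + 1)
(the +1 admits zero-count genes), resamples genes with replacement
within each class, and reads the two-sided p-value off the bootstrap
distribution of the difference of group means,
p = 2·min(P(Δ\*≤0), P(Δ\*≥0)) with a +1/(B+1) correction so p is never
exactly zero.  Genes (not variants) are the resampling unit: the
question is about gene-level load.  Selection classes are inputs; no
dN/dS computation is performed here.

## Synthetic generator

The generator emulates the structural features of the real inputs at
desk scale; one root seed drives per-component `SeedSequence` spawn
keys, so every output is byte-reproducible.

- **Catalog**: 300 SNV PVs in 40 genes, transition-biased (60%) so the
  deamination-confusable C>T / G>A classes are well represented; 10%
  benign/VUS rows exercise the classification filter; 71% of pathogenic
  PVs are flagged ancient-present.
- **Cohorts**: 400 ancient / 300 African / 600 non-African individuals;
  carried-PV counts Poisson (mean 0.5 ancient, 0.8 modern); each modern
  carried PV is drawn ancient-present with propensity 0.17 (African) or
  0.5 (non-African); carriers are heterozygous with probability 0.98.
  Ancient dates: 8.7% undated, an 8% tail uniform to 40,000 BP, the bulk
  uniform on [1,000, 5,000] BP.
- **Reads**: per-site depth 5 + Poisson(5) (minimum 5, mean 10 — typical
  usable shotgun coverage for this kind of presence calling), read length
  60, site offset uniform.  Deamination flips ref→alt at C>T (+ strand)
  and G>A (− strand) sites with probability δ·exp(−0.3·d) at distance d
  from the 5′ end (δ = 0.2); base miscalls follow each read's Phred
  quality (10^(−q/10)); 5% of reads are low-quality, 15% re-emitted as
  PCR duplicates sharing fragment and damage.
- **Species panel**: 8 clades × 5 species; sharing probability
  0.035·0.35^rank decaying from Fish toward Primate, 10% missing
  orthology — leaving ~80% of PVs absent from every species, the regime
  the cross-species analysis operates in.
- **Founder/selection tables**: 30 founder records with log-uniform ages
  on [150, 9,000] BP (80% points, 10% ranges, 10% bounds); selection
  classes 30/40/30% with Poisson count means 8/4/2.

What the generator does *not* emulate: linkage and haplotype structure,
population history (no coalescent), reference-bias and contamination in
ancient reads, gene length and mutation-rate heterogeneity, and
ascertainment differences between cohort sources.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
planted model, not robustness to every artifact of real data.

## Problem sizes and numerical choices

Test and acceptance runs use the default desk-scale conditions above:
1,500 simulated sites for genotype recovery, 200 rarefaction replicates
over sizes up to 600, 500 null datasets × 2,000 resamples for bootstrap
calibration, 10,000 replicates against the exhaustive 5-choose-2
enumeration oracle.  Percentages round half-up at the reported digit.
Ties in deduplication keep the first-seen read; ties in oldest-founder
selection keep the first record.  Degenerate inputs (empty pileups,
zero-discovery replicates, disjoint Venn sets, empty founder lists) are
flagged or excluded rather than erroring, except where a result would be
meaningless (zero denominator, oversized subgroup, empty bootstrap
group).

## Known limitations

The caller is a threshold rule, not a probabilistic damage model
(no Briggs-type likelihoods, no contamination estimate); zygosity at
depth ≤ 4 surviving reads is usually `present_unknown`.  Cohort-scale
published statistics that depend on the real quarter-million-person
cohorts (median sharing of 49.5% vs 17.3%, the P = 0.035 selection
contrast) are design targets for the machinery, not quantities this
package can recompute; the synthetic defaults reproduce their structure
(direction, separation, calibration), not their values.
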