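# Methods

## Reference model and coordinates

All coordinates are 1-based heavy-strand positions on a 16,569-bp
mitochondrial reference, with variants written `m.<pos><ref>><alt>`.
The genome is partitioned into seven functional regions — complex I,
complex III, complex IV, ATP synthase, rRNA, tRNA and non-coding — and
the partition is total and exclusive: every position resolves to exactly
one region. The control region wraps the origin and is modelled as two
segments (16024–16569 and 1–576); intergenic spacers fall into the
non-coding region. The only protein-coding overlaps retained are the two
classic ones, *MT-ATP8*/*MT-ATP6* and *MT-ND4L*/*MT-ND4*. Because both
members of each overlap share a region (ATP synthase and complex I
respectively), regional tallies are unambiguous; for locus-level
reporting an overlap position is assigned to the downstream gene
(*MT-ATP6*, *MT-ND4*), and `annotate_effect(..., all_frames=True)`
returns one call per reading frame. Three boundaries were simplified by
1–3 bp relative to the canonical annotation so that no other feature
pair overlaps: *MT-ATP6* ends at 9206 (dropping its 1-bp overlap with
*MT-CO3*), and the tRNAs *MT-TQ* and *MT-TY* start at 4332 and 5827.

### The packaged synthetic scaffold sequence

The packaged reference sequence
(`data/synthetic_rcrs_scaffold.fasta`) is **synthetic** — it is not
NC_012920. It keeps the canonical gene coordinates and pins the
reference base or full codon at every position used by the packaged
haplogroup tree or by documented disease-associated variants, so that
effect annotation at those sites is exact (m.9055G>A → p.Ala177Thr,
m.3480A>G → p.Lys58=, m.11299T>C → p.Thr180=, m.14167C>T → p.Glu169= on
the light-strand *MT-ND6*, m.3497C>T → p.Ala64Val, m.8836A>G →
p.Met104Val, m.14831G>A → p.Ala29Thr, m.11778G>A → p.Arg340His, and the
haplogroup-marker sites). Elsewhere, protein-coding genes carry a
CTA(-Leu) repeat in their own reading frame — any frame rotation of
which is stop-free under the vertebrate mitochondrial code, so the
overlap partners also translate cleanly — and remaining positions an
ACGT cycle. Consequences: codon-level effect calls at pinned sites match
the real rCRS; effect calls at arbitrary other sites are internally
consistent but not biologically meaningful; analyses that only depend on
positions, regions and allele pairs (Ts/Tv, rarity, burden, loads,
association statistics) are unaffected by the filler. Users with the
real NC_012920 FASTA can supply it via `load_gene_model`. The builder
(`mitovar.refdata`) validates the pinned sites and the absence of
internal stop codons on every regeneration, and a test asserts the
packaged file equals the programmatic build.

The vertebrate mitochondrial code (table 2: TGA = Trp, ATA = Met,
AGA/AGG = stop) is hard-coded; incomplete stop codons completed by
polyadenylation are irrelevant for substitution effect calls and a
variant falling in a trailing partial codon is reported as non-coding.

## Haplogroup assignment

The packaged mini-phylotree (`data/mini_phylotree.tsv`) is a coarse
synthetic stand-in for the full human mtDNA phylogeny, at two-to-three
level resolution: 12 reporting-level haplogroups (B, H, HV, I, J, K, N,
T, U, V, W, X) plus the internal nodes JT, U8 and U8b, with K derived
from U8b via U8 and U, J/T under JT, I/W/X under an N node and V under
HV. Marker sets are expressed relative to the packaged reference (an
H-lineage baseline, so the tree is rooted at H) and use canonical marker
positions where these are well established (e.g. 73/11467/12308/12372
for U; 3480/9055/14167 for U8b; 11299 for K; 72/4580 for V). A subject
is assigned the node maximising `matched − 0.5·missing` over cumulative
root-to-node marker sets; ties break to the deeper node, then
lexicographically. Hypervariable positions (309, 315, 515, 523, 3107,
16519) are excluded from both sides of the score via an ignore list —
standard practice that prevents recurrent mutations from accruing
spurious mismatch penalties. The λ = 0.5 mismatch penalty is this
package's own definition (external classifiers do not publish theirs);
it is validated by the recovery property — on marker-complete synthetic
cohorts assignment recovers the generating label for 100% of subjects —
not by agreement with any web service. Full-resolution trees in the same
TSV format can be supplied in place of the bundled one.

## Rarity, heteroplasmy and reported associations

Population frequencies enter as a per-allele percentage table; the rare
cutoff is inclusive (≤ 0.5% → rare, the conventional threshold for
"rare" mtDNA variation in GenBank-scale datasets). Variants absent from
the table are classed `unknown`, logged, and excluded from rare/common
tallies and share denominators rather than assumed rare — assuming rare
would inflate rare-variant counts whenever the table is incomplete.
Heteroplasmy is the mutant-allele percentage in (0, 100]; a call below
95% is heteroplasmic. The 95% default was chosen because reported
heteroplasmic calls in this setting reach 92% while "homoplasmic"
conventionally means no detectable wild type; it is configurable.
Reported-association flags are attached from a two-column list
(`data/reported_lhon_variants.tsv` bundles the documented LHON ones).

## Burden tallies and the exclusion rule

Tallies run per region and group in *occurrence* mode (every variant
instance) and *unique* mode (each distinct (position, alt) at most once
per group — "unique" is per group, matching how per-group unique counts
are reported). The primary mutation m.11778G>A is excluded from the
complex I, overall and overall-unique tallies: since every patient
carries it by ascertainment, leaving it in would manufacture a spurious
patient excess of transitions, rare variants and non-synonymous changes.
The exclusion is applied to all six counters for denominator symmetry;
this is a no-op beyond the stated three because the variant is a
transition, population-rare and non-synonymous. Group comparisons build
the 2×2 with the metric's two counters as rows and groups as columns and
delegate to the stats layer unchanged. Rare/common shares use occurrence
counts by default (consistent with the Fisher inputs); carrier analyses
ask whether a subject has ≥ 1 variant passing the active region, rarity
and score filters.

## Association statistics

- **Fisher exact (two-sided)**: point-probability ("minimum
  likelihood") definition — the sum of hypergeometric probabilities of
  all tables with the observed margins whose probability does not
  exceed the observed one (relative tie tolerance ~1e-7) — computed on
  the raw counts, never on corrected cells. This matches the behaviour
  of the major commercial statistics packages and reproduces the
  published borderline p-values 0.057 and 0.028. The implementation is
  scipy's; an independent enumeration oracle verifies exact agreement
  for every table with margins up to 15.
- **Odds ratio**: (a·d)/(b·c); with any zero cell, the
  Haldane–Anscombe correction adds 0.5 to *all four* cells first. This
  variant of the correction exactly reproduces published corrected ORs
  (11.000, 13.313, 2.742, 3.941). The correction affects OR and CI
  only.
- **Woolf (logit) CI**: `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` over the
  possibly corrected cells, with the exact normal quantile
  (z ≈ 1.959964 at 95%). Published bounds reproduce to three decimals
  below ~10 and to 0.5% relative on the large corrected upper bounds
  (the original rounding convention is unknown).
- **t-test**: pooled-variance two-sample test (df = n₁+n₂−2) on
  summary statistics, so published mean ± SD pairs can be re-tested;
  pooled reproduces the published load p-values (0.295, 0.531) and is
  the default, with Welch available by flag. Two zero-variance groups
  with equal means return p = 1 by convention.
- **No multiple-testing correction** is applied anywhere; all p-values
  are nominal, with significance conventionally read at p < 0.05.
- `counts_from_percent` reconstructs integer cells from printed
  percentages by half-up rounding and warns when the count does not
  round back to the printed percent. All bundled fixture tables pass
  this check and reproduce their printed ORs to three decimals.

## Variant loads

Per subject, the total load sums pathogenicity scores in [0,1] over
non-synonymous variants (primary mutation excluded); the threshold load
sums only scores strictly greater than 0.5. Scores are consumed from an
external table keyed by nucleotide or protein change (both accepted,
nucleotide key tried first); the scoring algorithm itself is out of
scope. Non-synonymous variants without a score are skipped with a
warning by default (strict failure available) — there is no principled
imputation for a missing predictor output.

## Synthetic cohorts

`SimulationConfig` defaults encode the emulated study conditions: 47
patients / 42 controls; per-group haplogroup frequency vectors matching
the observed distribution (patients: H 32%, U 19%, J 11%, K 11%, ...;
controls: H 43%, J 17%, U 12%, V 12%, K 0%, ...); every patient carries
m.11778G>A, heteroplasmic (uniform 70–95%) with probability 4/47 and
homoplasmic otherwise, all other variants homoplasmic; transition
probability 0.97 and non-synonymous fraction 0.40 among coding fillers,
matching the observed whole-mtDNA Ts/Tv (~35) and NS/S (~0.7) scale;
per-region per-subject Poisson rates of (rare, common) private variants
sized to the observed ~26 variants per subject, with the rare excess in
the complex IV region placed in controls (0.65 vs 0.35 expected rare
variants per subject, reproducing the reported ~19% vs ~34% rare shares
and ~30% vs ~45% carrier fractions at expectation); pathogenicity
scores Beta(2,3) (mean 0.4, giving total loads near 2). Rare variants
receive population frequencies uniform on (0.05, 0.5], common on
(0.6, 30], markers on (2, 45].

One RNG stream per cohort, seeded from the config and consumed subject
by subject (patients first), makes cohorts reproducible and append-
stable. Within a subject: haplogroup draw, marker variants, then
per-region filler; each first-seen variant draws its frequency (and
score if non-synonymous) at that point. Filler positions are uniform
within the region, excluding the subject's used positions, all tree
marker positions and the primary-mutation site — the latter two so that
marker sets stay clean and haplogroup recovery is exact by construction.
Coding fillers rejection-sample (up to 60 draws) toward their target
synonymous/non-synonymous category.

What the generator does **not** emulate: phylogenetic linkage beyond
the marker sets (private variants are independent across subjects),
realistic site-specific mutation spectra, heteroplasmy outside the
primary mutation, indels and rearrangements, and sequencing error.
Passing tests therefore demonstrate the correctness and calibration of
the analysis machinery under the stated statistical structure, not
robustness to real-data artefacts such as alignment error or
frequency-table bias.

## Problem sizes and numerical choices

The test suite runs the paper-scale cohort (47/42) for pipeline
round-trips, a 500-per-group cohort for parameter recovery (shares
within 3 binomial SE of configured rates), and null cohorts (identical
group processes) until ≥ 1000 per-SNV Fisher tests accumulate,
asserting a ≤ 7% rejection rate at nominal 0.05 — the exact test is
conservative, so the realized rate sits well below nominal. Exhaustive
checks (region partition over all 16,569 positions; Fisher vs
enumeration over all 18,495 tables with margins ≤ 15) run in seconds.
Floating-point ties in the Fisher definition use the ~1e-7 relative
tolerance stated above; odds-ratio and CI reproduction is asserted at
the printed precision (3 decimals, or 0.5% relative for large corrected
upper bounds). Degenerate inputs are defined explicitly: ts/tv ratio is
undefined (rendered "n/a") when there are no transversions; rare/common
shares are undefined for empty regions; a zero-variance t-test with
equal means returns p = 1.

## Known limitations

- The scaffold sequence limits biologically meaningful effect calls to
  the pinned sites; supply the real NC_012920 FASTA for full-genome
  effect annotation.
- The mini-phylotree is coarse; sub-haplogroup strings (e.g. "B4c1b2")
  are out of scope, and subjects of lineages missing from the tree
  would be absorbed into the nearest bundled clade.
- Raw counts behind some published regional odds ratios cannot be
  uniquely reconstructed from printed percentages alone; such rows are
  exercised through summary-statistic pathways, not asserted cell by
  cell.
- Indels, large deletions and RNA secondary-structure impact are out of
  scope.
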