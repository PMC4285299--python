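# Methods

## Coordinate and data conventions

All genomic coordinates in the data model are 1-based and inclusive at both
ends (the VCF/HGVS convention); BED input is converted from 0-based
half-open on read and back on write. Adjacent (touching) intervals merge
into one region, since coverage and target accounting treat contiguous
bases as a unit. Strand is carried on transcript models only for
transcript-relative naming; it never influences filtering. The missing
value sentinel in every tabular format is `.`; a missing minor allele
frequency is `None` in memory and is never coerced to 0 — a variant with no
population frequency is a novel variant and must survive frequency
filtering.

The annotated-variant table dialect (18 mandatory tab-separated columns,
documented in `exomesift.readwrite`) is a declared stand-in for the kind of
report a commercial annotation engine exports; the true schemas of such
engines are proprietary and partially collapsed for display, so the package
defines a minimal faithful dialect rather than reconstructing one.

## The filter cascade

The cascade applies an ordered list of row-dropping predicates, recording
variants-in/variants-out per step. Because no step may create or mutate a
variant, the step outputs are nested subsets, counts are monotone
non-increasing, and the surviving set is invariant to input row order.
Counts *are* order-dependent, so the step order is stored with the
parameters as part of the audit record. The default order is quality →
region → consequence → frequency → protein-altering → inheritance.

Defaults and their reasoning:

- `min_quality = 0`, `min_depth = 0` — the quality step is a no-op unless
  the user sets thresholds, so a default run reports exactly the
  region→…→inheritance reductions a diagnostic summary table shows.
- `splice_window_bp = 10` — an intronic variant within 10 bp of an exon
  boundary is a splice-site candidate and is rescued regardless of its
  consequence class; the boundary is inclusive (±10 kept, ±11 dropped).
- `max_maf = 0.10` — variants with a known dbSNP MAF ≥ 0.10 are too common
  to cause a rare Mendelian disorder and are excluded; the cut is applied
  as ≥ (a MAF of exactly 0.10 is excluded). Missing MAF survives.
- The protein-altering step excludes synonymous variants and keeps
  missense, nonsense, frameshift, in-frame indel and splice-region rows;
  intronic/UTR rows not already removed upstream pass through. A splice
  window rescue can carry a synonymous-annotated row forward, but the
  protein-altering step will still drop it.
- Compound-heterozygote detection is deliberately unphased: a gene with
  two or more distinct heterozygous variants is *possibly* biallelic.
  Short-read panels cannot phase, and trio data is out of scope, so the
  filter over-retains rather than over-drops. Rows with unknown zygosity
  are dropped by every active inheritance mode (they cannot support a
  zygosity argument) and kept by mode `none`.
- Gene-symbol matching is case-insensitive; panel lists are hand-curated.

Steps with nothing configured (no regions/panel; inheritance `none`) are
skipped rather than logged as identity, and calling the region filter with
an empty panel *and* empty regions is an error — it would silently drop
every variant.

## cDNA HGVS indel parsing

The grammar covers the indel subset of `c.` nomenclature: `del`, `dup`,
`ins`, `delins`, single positions or ranges, with intron offsets
(`c.207+1`, `c.1668-19`). Substitutions, inversions and `*`-anchored UTR
positions are rejected with an error naming the offending token — they
belong to the VCF path. The affected-reference-base count of a range is
`(end.anchor − start.anchor) + (end.offset − start.offset) + 1`, which is
valid exactly when the range is genomically contiguous (offsets measured
from the two anchors of a single exon/intron junction). A range that
provably crosses an entire intron (positive start offset and negative end
offset) cannot be sized from cDNA coordinates alone and raises rather than
mis-sizing. A delins affects its deleted span; a pure insertion affects 0
reference bases, with the inserted length reported separately. The bundled
24-variant known-indel panel (`exomesift.datasets.load_known_indels`) is
the parser's regression fixture: class and affected-base columns are
reproduced for every row.

## Pindel-style event blocks

The block grammar is a `#` separator line, a whitespace-separated header
keyed on the literal tags `NT`, `ChrID`, `BP`, `Supports`, a reference
line, and one line per supporting read at its placement offset. Parsing is
keyed on the tags, not on field positions, so minor field-order drift
between producer versions is absorbed; unmodelled header fields are kept as
opaque text and written back verbatim, making parse→write→parse stable at
the byte level. Breakpoint convention: `bp_start` is the last reference
base before the event, `bp_end` the first after, so a deletion removes
`bp_end − bp_start − 1` bases (enforced at construction). Region filtering
keeps an event when either breakpoint lies in a target (a large deletion is
captured whenever one end is in the pull-down region); a stricter
both-ends rule is available by flag. Identical events reported in several
source files are kept and grouped by (type, chrom, breakpoints, inserted
sequence) rather than silently deduplicated.

## Anchored split-read deletion detection

For a fragment straddling a deletion, the junction-crossing read cannot be
placed by a gapless aligner but its mate maps cleanly. The detector builds
a search window from the anchor: with `insert_mean` the expected outer
fragment length and `L` the read length, a `+`-strand anchor at position
`A` implies an expected mate start `A + insert_mean − L`, and the window
spans from `max_event` before that point to `insert_mean + max_event`
beyond it (a deletion pushes the mate's distal placement downstream); the
`−` case mirrors upstream. The window size is the constant
`insert_mean + 2·max_event + L` before clipping at position 1.

Inside the window the unplaced read is split exactly: a prefix placed at
one offset, the suffix strictly downstream, both exact matches, with at
least `min_flank` (default 15) bases per side. Among valid splits the most
balanced one wins; remaining ties go to the smallest deletion start, and
calls are left-normalised (slid to the smallest start while the base before
the deletion equals its last base), matching VCF left-alignment. Identical
(start, end) solutions across reads are clustered; clusters of at least
`min_supporting_reads` become calls. Exact matching is a deliberate
desk-scale choice: on error-free synthetic reads it makes breakpoint
exactness a testable property (zero-tolerance equality over many seeds)
instead of a statistical claim. `max_event` defaults to 1000 bp; window and
flank parameters are package choices, not reconstructions of any
production caller's internals.

The capture-edge behaviour falls out of the model: a deletion is
recoverable iff anchors on at least one breakpoint flank are captured,
since an uncaptured fragment is never sequenced.

## Autozygosity mapping

`find_runs` is a transparent scan, not a clone of any published array
tool: per chromosome, maximal marker windows containing at most `max_het`
heterozygous calls (a genotyping-error allowance), with no-calls neither
breaking nor extending a run; windows are trimmed to homozygous endpoints,
and overlapping maximal windows — alternative placements of the same error
budget over one underlying tract — are merged so each tract is reported
once. After merging, a run's total exception count can exceed `max_het`;
`max_het` is a per-window allowance, which we judged more useful than
reporting a ladder of overlapping window variants. Defaults: `min_markers`
50, `min_length_bp` 2 Mb, `max_het` 2, all exposed; thresholds for
"apparently autozygous" are package choices.

`concordant_regions` intersects the affected siblings' runs, requires
identical homozygous alleles at ≥ 95 % of jointly homozygous markers, and
removes regions where an unaffected sibling is homozygous-identical across
the region (such a region cannot harbour the recessive allele).
`restrict_variants_to_regions` then composes the cascade's region filter
with a homozygous + protein-altering + rare preset — the query used to
extend a gene-panel search into candidate autozygous intervals.

## Coverage acceptance

Per-base depth over each target gives minimum, mean (as an exact integer
depth sum over the target length) and the fraction of bases at or above
each threshold. Bases absent from the depth track have depth 0, never
interpolated, and a target on a chromosome missing from the track is
flagged separately so absent data is not read as a coverage failure. The
default acceptance rule is per-base at 50-fold with required fraction 1.0 —
a single under-covered base fails the target's genotype acceptance —
relaxable for sensitivity-style reporting. Depth-mass conservation (sum of
per-target integer sums equals the track's mass over the targets) is exact
and tested as such.

## Synthetic data: what it emulates and what it does not

Every generator is deterministic in its seed and emits a truth record;
recovery tests consume the truth records rather than re-deriving them.

- **Cohorts** emulate the *composition* of an exome screen for a recessive
  disorder: category probabilities are calibrated so that, in expectation,
  ~33,143 variants contain ~94 in an 18-gene panel, ~66 exonic/splice, ~15
  rare, ~10 non-synonymous. Inheritance-step survival depends on gene-level
  grouping, so only the first four ratios are exact per-variant
  expectations. Quality and depth are drawn high enough that the no-op
  default quality step is realistic. Planted causal variants are
  high-quality, rare, nonsense, and consistent with the requested
  inheritance mode. Not emulated: linkage structure, annotation errors,
  systematic artefacts, shared variants between cohort members.
- **Deletion read sets** produce error-free pairs whose unplaced mate
  crosses the junction with ≥ 20 bp on each side; capture is modelled by
  rejection-sampling fragments whose anchoring read lies in the mask. The
  truth breakpoints are left-normalised, since that is the only canonical
  representation of a deletion inside a repeat. Not emulated: sequencing
  error, soft-clipping, mapping quality, coverage fluctuation — so passing
  tests demonstrate algorithmic correctness, not robustness to noisy data.
- **Pedigree genotypes** plant a shared homozygous haplotype in affected
  samples with a 0.2 % heterozygous-error rate (typical SNP-array
  discordance) and 1 % no-calls. Tract boundaries are made
  marker-identifiable by forcing `max_het + 1` flanking markers just
  outside each end to be heterozygous in affected samples — an
  idealisation of the heterozygote-dense background flanking a real
  identity-by-descent boundary. Between-marker boundaries are inherently
  unidentifiable from genotypes, so on real data boundary resolution is
  set by the nearest discriminating markers, typically coarser than the
  one-spacing recovery the tests demonstrate.
- **Depth tracks** plant low-coverage targets at a depth far enough below
  the acceptance threshold (10× ± 20 vs 100× ± 20 at a 50× threshold) that
  planted and failing sets coincide exactly.

## Numerical and degenerate-input choices

Ties in split alignment: balance first, then smallest deletion start, then
smallest gap — determinism over any claim of biological preference. Empty
inputs are legal everywhere they are meaningful (empty tables, empty event
directories, zero-variant cohorts) and produce empty outputs, not errors;
operations whose misuse would silently destroy data (region filter with no
criteria, duplicate keys in an observation-count table, unknown keys or a
version mismatch in a parameters file) fail loudly instead. Problem sizes
in the test suite (2,000-variant cohorts for seeded cascade sweeps, 5 kb
references for read simulation, 3,000-marker chromosomes) are chosen to
exercise every code path at desk scale; the cohort generator's default
remains the full ~33k-variant composition.

## Known limitations

No phasing, pedigree likelihoods or IBD scores; no protein-level HGVS
derivation; no genomic↔cDNA projection (that needs transcript sequence);
the split-read detector handles deletions only (no insertions, tandem
duplications or inversions) and does not ingest real alignments; no VCF
writing; no liftover or multi-build support (hg19-style coordinates are
assumed but never enforced).
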