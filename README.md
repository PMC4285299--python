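# exomesift

Diagnostic variant filtering for targeted-capture and exome sequencing, as a
scriptable library and CLI.

Clinical laboratories that sequence gene panels or exomes face a reporting
bottleneck: a single exome yields tens of thousands of annotated variants,
of which at most a handful are plausibly causal for a rare Mendelian
disorder. `exomesift` implements the interactive triage stage of such a
pipeline as reproducible batch operations with a written audit trail:

- **Filter cascade** — an ordered sequence of predicate filters over
  annotated variants (quality/depth, gene panel or genomic regions,
  exonic/splice-site consequence with a ±10 bp splice window, dbSNP minor
  allele frequency < 0.10, synonymous exclusion, inheritance model), with a
  per-step in/out count report. Inheritance modes: *dominant* (heterozygous
  only), *recessive with consanguinity* (homozygous only), and *recessive*
  (homozygous, plus possible compound heterozygotes — genes carrying ≥ 2
  distinct heterozygous variants, unphased).
- **cDNA HGVS indel parsing** — deletions, duplications, insertions and
  delins with intron offsets (`c.197_207+20del`), classified I/D/D-I and
  sized in affected reference bases.
- **Pindel-style event triage** — parsing of textual indel event blocks,
  filtering by supporting-read count and target overlap (an event is kept
  when *either* breakpoint is in a target: large deletions are captured as
  long as one end is in the pull-down region), naming relative to a
  transcript's exon/intron structure, and fixed-width read-vs-reference
  rendering.
- **Anchored split-read deletion detection** — a desk-scale detector for
  deletions whose spanning reads a gapless aligner cannot place: the mapped
  mate anchors a bounded search window, the unplaced read is exact-match
  split-aligned inside it, and clustered splits give breakpoints at
  nucleotide resolution.
- **Autozygosity mapping** — runs of homozygosity from SNP genotype tables,
  intersected across affected siblings and screened against unaffected
  ones, then used to restrict variants with a homozygous + deleterious +
  rare preset.
- **Coverage acceptance** — per-target minimum/mean depth and
  fraction-at-threshold from a per-base depth track, with a 50-fold
  per-base acceptance default.
- **Synthetic data** — seed-deterministic generators for every input, each
  with a machine-readable truth record (planted causal variants, deletion
  breakpoints, autozygous tracts, low-coverage exons), standing in for
  patient data.

## Worked example

Size and classify indels from their cDNA HGVS descriptions:

```sh
$ exomesift hgvs c.1175_1214del c.197_207+20del c.7762_7764delinsTT
D 40
D 31
D/I 3
```

`D 40` reads: a deletion affecting 40 reference bases. The second case
crosses an exon/intron junction (`207+20` is 20 bases into the intron), so
the span is 11 exonic + 20 intronic = 31 bases. The delins deletes 3 bases
and inserts `TT`.

Generate a synthetic exome cohort with a planted homozygous causal variant,
build a parameter file for an 18-gene recessive query, and filter:

```sh
$ exomesift synth cohort --seed 11 --mode recessive_consanguineous --out-dir scen/
$ python -c "
from exomesift.readwrite import FilterParameters, save_parameters, read_gene_panel
save_parameters(FilterParameters(gene_panel=read_gene_panel('scen/panel.txt'),
                                 inheritance_mode='recessive_consanguineous'),
                'params.txt')"
$ exomesift filter scen/cohort.tsv --params params.txt \
      --out survivors.tsv --report report.tsv --log runlog.jsonl
quality: 33144 -> 33144
region: 33144 -> 79
consequence: 79 -> 53
frequency: 53 -> 11
protein_altering: 11 -> 9
inheritance: 9 -> 2
survivors: 2
```

Each line is one cascade step with its in/out variant count — the shape of
the reduction table a diagnostic report is built on (~33k exome variants
fall to a handful after panel, consequence, frequency and zygosity
filters). The planted causal variant's key is listed in `scen/truth.json`
and is always among the survivors. `--log` appends a JSON-lines entry with
input digests and step counts, so any run can be reproduced from its log.

Simulate a capture-edge deletion and call it back at base resolution:

```sh
$ exomesift synth deletion --seed 6 --out-dir del/
$ exomesift splitread del/reference.fa del/pairs.tsv --min-reads 5 --out calls.tsv
1 deletion call(s)
$ cat calls.tsv
chrom	del_start	del_end	length	supporting_reads
ref	1255	1764	510	10
```

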