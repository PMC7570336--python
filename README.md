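# barcauth

Multi-locus DNA-barcode authentication of herbal raw materials, built around
the St John's Wort (*Hypericum perforatum* L.) case study.

## The problem

Pharmacopoeial quality control of a medicinal plant asks a narrow question:
is this material the declared target species, or one of a known panel of
adulterants?  A barcode chosen for authentication does not need to resolve a
whole genus — it needs a small number of sites that reliably separate the
target from its close relatives (for St John's Wort, chiefly the sister
species and known adulterant *H. maculatum*).  `barcauth` implements that
applied-barcoding workflow end to end for people building or auditing such
tests: curating a panel database from noisy repository sequences, defining a
reference barcode as a testable quality standard, and combining several
partially informative loci into a single identification verdict.

## What it computes

* **Curation** (`barcauth.curation`) — outlier screening of conspecific
  accessions (singletons below 95% global-alignment identity to every other
  accession are discarded), IUPAC consensus and subtype construction by
  single-linkage clustering, discriminating-site reports (sites unique to the
  target vs sites that only separate a species pair), and variability-hotspot
  scans.
* **Reference matching** (`barcauth.refmatch`) — the reference barcode is a
  case-encoded IUPAC pattern: lowercase *essential* bases must match exactly
  (ambiguity-aware), and overall identity across the pattern must reach the
  threshold (default 95%, inclusive).  A test sequence passes iff

  `pass  ⇔  (no essential-base violation)  ∧  (identity ≥ 0.95)`

  with segments aligned semi-globally (free end gaps on the test side) and
  both strands tried.
* **Haplotype keys** (`barcauth.haplotype`) — the rbcL key maps seven sites
  (66, 180, 263, 300, 372, 378, 492 in the panel coordinate system) to core
  types 1 / 2 / intermediate 1-2, with two perforatum-marker SNPs layered on
  top (`1p` = both markers, `1(p)` = one).  Every one of the 4^7 possible
  state vectors receives exactly one call.
* **RNA structure characters** (`barcauth.rnastruct`) — base-pair-maximizing
  hairpin folding, psbA 3′ UTR stem-loop extraction between conserved anchors
  with LONG/SHORT classification (the diagnostic deletion truncates the
  stem), compensatory-base-change (CBC / hemi-CBC) counting between aligned
  ITS2 structures, and an invertible 12-letter sequence+structure alphabet.
* **Verdicts** (`barcauth.verdict`) — the rule cascade that combines ITS
  match, stem class and rbcL type into the codes `P p M m U` (confirmed /
  possible target, confirmed / possible adulterant, undetermined).
* **Synthetic data** (`barcauth.synthetic`) — seeded generators for panels
  with planted species SNPs and subtypes, haplotype-bearing rbcL sequences,
  stem-loop spacer variants and a CBC clade-gradient structure panel, plus
  the checked-in transcription of the case study's 38-sample field table.

## Worked example

Decide the packaged 38-sample Lithuanian field collection (22 nominal
*H. perforatum*, 16 nominal *H. maculatum*) and print the verdict tally:

```sh
barcauth report --input src/barcauth/data/test_collection_characters.tsv
```

```json
{
  "Hypericum maculatum": {
    "M": 10,
    "m": 5,
    "p": 1
  },
  "Hypericum perforatum": {
    "P": 11,
    "U": 6,
    "p": 5
  }
}
```

Reading: 10 of 16 maculatum-labelled samples are confirmed adulterant (ITS
matched the *H. maculatum* reference and the long psbA stem corroborates);
11 of 22 perforatum-labelled samples are confirmed target by the ITS
reference match; the `p`/`m` rows lack an ITS sequence and are called from
the stem-loop character alone; `U` rows are undetermined (failed ITS, or no
data, or conflicting characters).

Classify the packaged stem-loop archetypes:

```sh
barcauth stemloop --input src/barcauth/data/psba_archetypes.synthetic.fasta
```

```
id	class	stem_bp	loop	archetype	agrees
long_archetype	LONG	12	AAA	long	True
short_archetype	SHORT	6	AAA	short	True
```

The short form's 6-bp stem (vs 12 bp) reflects the diagnostic deletion; the
3-base apex loop (AAA or UUU) is reported separately and never affects the
class.

Other subcommands: `curate`, `consensus`, `sites`, `match`, `haplotype`,
`cbc`, `decide`, `simulate` (see `barcauth --help`).

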