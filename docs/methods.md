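# Methods

This note documents the models and procedures implemented in `barcauth`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions.  All coordinates throughout the
package are 1-based inclusive.

## Scope and design of the pipeline

The package implements a diagnostic (botanical-key style) approach to
species authentication rather than distance-based identification: a small
number of *essential* discriminating bases decide the call, and an overall
identity requirement merely contextualizes them.  The pipeline stages mirror
the applied-barcoding decision workflow: panel definition → database
curation → site discovery → reference-barcode definition → per-locus
characters → combined verdict.  Wet-laboratory steps (extraction, PCR,
sequencing, trace assembly) are out of scope; primer information is carried
only as inert reference data.

## Curation

**Pairwise identity.**  Identity between unaligned sequences is
matches / aligned columns (gap–gap columns excluded) on a global alignment
scored match +1, mismatch 0, gap −1 (Biopython `PairwiseAligner`).  No
standard definition exists for "percent identity"; this is the conventional
alignment-column definition, and the scoring is configurable in code.  Rows
already in one alignment are compared column-wise with the same convention.

**Outlier screen.**  Unreliable accessions are typically singletons below
95% identity to every conspecific sequence.  Records are single-linkage
clustered at the identity threshold (default 0.95); singleton clusters are
discarded *only when a multi-member cluster exists*.  Two mutually distant
sequences with no core group are kept — they are evidence of intraspecific
variation, not of an outlier.  This local filter replaces remote
distance-tree screening so the pipeline has no network dependence; the
criterion (95%) is the same.  The operation is idempotent.

**Consensus.**  Per column, gaps are ignored in frequencies unless they
exceed 50% of rows, in which case the column is dropped and its coordinate
logged (the output then lives in a shorter coordinate system — the dropped
list is the map back).  Ambiguity codes in input rows contribute
fractionally to each base they denote.  With ambiguity floor *f* (default
0.25): a base at frequency ≥ 1 − *f* is emitted alone, otherwise the minimal
IUPAC code covering all bases at frequency ≥ *f*.  At *f* = 0 the consensus
is compatible with every input row at every column; at *f* > 0 rare variants
are deliberately excluded, which is the point of the floor.

**Subtypes.**  Intraspecific variant groups ("subtypes") are single-linkage
clusters at `link_identity` (default 0.995, i.e. rows within ~3–4
substitutions over a ~700-nt ITS region link together while templates
differing at 7 sites do not).  Clusters are ordered by (size desc, consensus
lexicographic, member ids) so that roman-numeral labels are reproducible and
invariant to input row order.

**Discriminating sites.**  For a target species: a column is *unique* when
all target rows share a compatible state and every non-target row is
incompatible with that shared state; a column discriminates a species *pair*
when every row of one species is incompatible with every row of the other.
All comparisons are IUPAC-expansion based.  Columns containing any gap are
excluded by default (indel-containing columns are handled by the stem-loop
character instead, where indels are the signal).  Hotspot scans score
windows by the fraction of variable columns (≥ 2 distinct non-gap symbols)
and flag windows at or above a configurable quantile (default 0.9) of the
score distribution.

## Reference-barcode matching

A reference barcode is one or more case-encoded IUPAC segments (the
case-study standard uses two: one covering the main ITS1 variable regions,
one covering ITS2).  Matching per segment:

1. the segment pattern is aligned semi-globally to the test sequence (edlib
   infix mode: free end gaps on the test side, unit edit costs,
   IUPAC-compatible characters count as matches, deterministic leftmost
   traceback);
2. identity = compatible pattern columns / pattern length; unaligned or
   gapped pattern positions count against identity;
3. an essential position fails iff its aligned test base is absent or
   incompatible with the (possibly ambiguous) essential code.

Overall identity combines segments by length-weighted mean (default) or
per-segment minimum — the published criterion does not state which, so both
are provided; the weighted mean is the default because a single overall
"95% match" most naturally reads as a whole-barcode quantity.  The threshold
comparison is inclusive (≥ 0.95): "a 95% match" is read as met at exactly
95%.  Both strands are evaluated and the better-scoring orientation is
reported (ties favour forward).  A gap at an essential base is a failure; a
gap at a non-essential base is an identity mismatch only.

Consequences, enforced by tests: an essential violation vetoes a pass at any
identity; adding mismatches never converts fail → pass; passing at threshold
*t* implies passing at any *t′* ≤ *t*.

## rbcL haplotype key

The key file (JSON) carries its coordinate-system name, the mapped
positions, the consensus base per position, prioritized core-type patterns
and marker SNPs.  The packaged rbcLa key: positions 66, 180, 263, 300, 372,
378, 492 with consensus C C A A A A A; type 1 requires the derived states
300=G and 372=C; type 2 requires 378=G and 492=T; a vector matching neither
pattern but all-consensus at the five core sites is the intermediate 1-2; 
anything else is *novel* (a category added because haplotypes unseen in any
panel accession are exactly what a field assay must flag rather than
force-fit).  180=T co-occurs with type 1 in most species but is not
diagnostic: one panel species carries the type-1 pattern with 180 at
consensus, so requiring it would misclassify a published row.  Core patterns
are evaluated in priority order (1 before 2), which decides vectors carrying
both derived patterns; the published reference rows include a sample with
the type-1 triple plus 378=G that is typed 1, fixing this precedence.
Marker SNPs (66=T, 263=T) are counted independently of the core type; a
type-1 call displays `1p` with both markers and `1(p)` with one — position
66 is used as the canonical single marker because it was observed in every
target accession.  Missing or non-ACGT states at core sites degrade the call
to "insufficient data".

The en dash in printed labels ("1–2") is normalized to ASCII `1-2`
throughout.

## RNA structure characters

**Folding.**  `fold_hairpin` maximizes base pairs (Nussinov dynamic program)
over canonical pairs including G·U wobble (the external folder used for the
published structures allows them; configurable), with a minimum hairpin loop
of 3 — matching the observed 3-base AAA/UUU apex loops.  Base-pair
maximization was chosen over nearest-neighbour free-energy folding because
the diagnostic character is stem length, which the maximum-pairing structure
of these short anchored regions captures; externally computed
minimum-free-energy dot-brackets can be supplied anywhere a structure is
accepted, as a parity check.  The traceback is deterministic: at co-optimal
ties the 3′ base is paired rather than left unpaired, with the 5′-most
admissible partner, which keeps helices contiguous.

**Stem-loop extraction.**  The psbA 3′ UTR stem-loop sits in a variable
region between two conserved flanks; each anchor motif must match exactly
once (IUPAC-aware search) or the operation fails loudly listing the matches.
The region between anchors is folded and the *terminal helix* measured: the
chain of nested pairs enclosing a hairpin loop with no multiloop branching
(interior loops and bulges allowed), taking the longest such helix.  Class
SHORT iff stem_bp ≤ 8 (default): the packaged archetypes have 6 bp (short,
deletion present) and 12 bp (long), so 8 separates them with a ±2 bp margin;
the threshold is configurable because real spacers vary.  Alignment to the
two archetype regions is reported as corroborating evidence (closest
archetype + agreement flag), but classification uses the fold: deletion
evidence depends on which archetypes are packaged, the fold does not.
Loop-sequence changes (AAA ↔ UUU) cannot change the class because the apex
is unpaired by construction — the stem arms contain no U partner for an A
apex, and pairing a U apex against a stem G always costs at least one
stem pair.

**CBC counting.**  Over the column pairs base-paired in *both* structures of
a common gapped frame: a CBC when the rows differ at both partners, a
hemi-CBC at exactly one.  Counts are symmetric, zero on identical rows, and
cbc + hemi ≤ shared pairs.  Exact CBC integers against the published panel
are not reproducible here — those inputs live in an external ITS2 structure
database — so the package validates CBC counting by properties and by a
synthetic clade-gradient panel: same-clade species planted with 0 CBCs
relative to the target, then 1 / 2 / 4–5 with increasing clade distance,
including one anomalous clade-D species at 5 (mirroring the published
observation that CBCs track clades, with one anomaly likely reflecting a
misidentified accession).

**12-letter encoding.**  Each (base, pairing-state) pair maps to one letter:
unpaired A C G U stay themselves; opening partners map to E F I K; closing
partners to L M P Q.  The mapping is documented here and invertible on its
own; it is internally consistent but not claimed identical to any external
tool's alphabet, which is not published in machine-readable form.

## Verdict engine

The cascade is listed in `barcauth.verdict`'s docstring and `--rules`.  Two
reconstructed choices deserve emphasis:

* the rbcL character influences only the M → m downgrade (an adulterant ITS
  match with the anomalous intermediate 1-2 type is reported as *possible*
  adulterant).  The marker SNPs proved unreliable on field samples — most
  adulterant-labelled samples carried the "target" 1p haplotype — so the
  haplotype is treated as corroborative, never decisive;
* with no ITS data and a long stem, a nominally-adulterant sample is called
  `m` but a nominally-target sample `U`.  This asymmetry is transcribed from
  the case-study truth table, not from a stated rule; the emitted rationale
  flags it as reconstructed.

A sample whose ITS sequence was obtained but failed all references is `U`
regardless of stem class: a failed primary barcode is treated as positive
evidence of trouble that supporting characters cannot override.  The
published prose differs from its own table in two tallies (12 vs 11
ITS-confirmed target samples; 20 vs 19 short-stem target samples); the
engine reproduces the table, and the discrepancy is simply noted here.

## Synthetic data

The generators define the study conditions used by the tests: a 20-species
panel (the real panel's names and metadata ship as a fixture) with 2 planted
species-specific SNPs per species; 3 target and 2 adulterant ITS subtypes
differing at 7 and 4 planted columns respectively, 4 accessions per subtype
and 2 per other species over 700 sites; substitution noise at 1 expected
substitution per accession (set to 0 for exact parameter-recovery checks);
30% ITS dropout in field-collection emulation, matching the ~70% sequencing
success of the case study; rbcL label frequencies weighted to the field
observations (target mostly `1p`; adulterant majority `1p` despite the
species — the published anomaly).  Randomness is exclusively numpy PCG64
seeded from `SimConfig.seed`; fixed seed ⇒ byte-identical output across
platforms.  Noise is substitution-only except in the psbA module, where
indel-like variation is represented by homopolymer run-length jitter in the
A/T-rich flanks — keeping planted-truth bookkeeping exact for the alignment
modules while exercising the stem-loop character's robustness.

What the generators do *not* emulate: phylogenetically realistic divergence
(no coalescent), hybridization/apomixis, chloroplast capture, sequencing
error profiles, or real indel processes inside alignments.  Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated statistical structure, not field performance on real material.

The 38-sample field character table is a checked-in transcription (not
generated), guarded by a SHA-256 checksum, with an `its_closest` column
disambiguating failed-ITS outcomes: adulterant-labelled failures matched the
adulterant reference (→ MATCH_ADULTERANT) while target-labelled failures
matched nothing (→ FAIL).  The packaged reference barcode and psbA
archetypes are synthetic constructions with the documented properties (the
published figure content is not machine-readable); their filenames and
docstrings say so.

## Numerical conventions and degenerate inputs

* Thresholds are compared inclusively (≥) everywhere.
* Clustering, consensus and verdicts are deterministic under row
  permutation; documented tie-breaks (lexicographic / 5′-most / forward
  strand) decide every tie.
* Empty inputs raise errors rather than returning empty results, except
  where an empty result is meaningful (empty verdict table → header-only
  report with zero tallies).
* Problem sizes in the test suite (700-site panels, ≤ 14-nt exhaustive fold
  enumeration, 1000 random CBC pairs) were chosen so the whole suite runs in
  seconds while the enumeration oracles remain genuinely exhaustive.

## Known limitations

* The Nussinov fold is O(n³) in pure Python; it is intended for anchored
  stem-loop regions (tens of nt), not whole spacers or genomic windows.
* Reference matching assumes the barcode segments occur once in the test
  sequence; tandem duplications would silently match the better copy.
* The outlier filter's singleton rule can keep a pair of mutually similar
  but jointly unreliable accessions; with very few conspecific sequences no
  statistical screen is possible, which is exactly the situation the
  workflow warns about.
* The verdict cascade is a faithful reconstruction of one case study;
  applying it to another species pair requires revisiting rule 4's
  asymmetry and the role of the supporting loci.
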