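# Methods

## Data model

One `CDSRecord` per annotated CDS feature that carries a
`/translation` qualifier. Pseudo genes (`/pseudo`, `/pseudogene`) and
translation-less CDS are skipped and counted; the `/translation`
qualifier is authoritative — no on-the-fly translation is attempted, so
a disagreement between the located DNA and the annotated protein is
preserved, not "fixed". Source-feature annotation (organism,
`taxon:` db_xref, entry length, LOCUS date) is attached to every CDS of
its entry. Coordinates are 1-based inclusive throughout (the GenBank
convention); any half-open arithmetic is internal to the splicer.

### Feature locations and partial ends

The location parser covers the grammar ordinary CDS annotation uses:
positions, `a..b` ranges, `join()`, `complement()` and the `<`/`>`
open-end markers. `order()`, `bond()` and mixed-strand joins are
rejected — trans-spliced genes are out of scope. Both minus-strand
spellings are accepted: `complement(join(...))` (elements in genomic
order, reversed to coding order by the complement) and
`join(complement(...), ...)` (elements already in coding order, the
convention third-party parsers use). Intervals are stored in coding
order; splicing concatenates interval slices, reverse-complementing
minus-strand slices.

`<` and `>` mark the genomic-left and genomic-right coordinates as
open. Their mapping to biology is strand-corrected: on the plus strand
`left_open` means the 5′ end is incomplete; on the minus strand the
genomic-left marker is the 3′ end. The flat-file format itself does not
spell this out per strand, but strand correction is the only reading
under which "incomplete 5′ end" means the same thing for both
orientations, so `partial5`/`partial3` are defined that way and the
8-case {left, right} × {strand} grid is pinned in tests.

### Hashes and derived fields

Sequence identity uses MD5 of the uppercased, whitespace-stripped
sequence, with trailing `*` stops stripped from proteins, so `acgt`
and `ACGT` hash identically (lookup is case-insensitive but otherwise
exact). GC percent counts G, C and S (strong) in the numerator and all
characters in the denominator; other ambiguity codes dilute, not
inflate, the percentage. RefSeq membership is inferred from the
accession shape (letters + underscore + digits): the underscore does
not occur in classical INSDC accessions, making it a reliable marker.
Ambiguity is defined as any character outside {A,C,G,T} for DNA and
outside the 20 standard amino acids for protein — the simplest rule
that is exactly testable. `/codon_start` > 1 does not trim the stored
CDS; the record keeps the literal located span with `codon_start` as
annotation.

## Store

A single sqlite3 file (zero-install, reproducible builds) holds the
records plus the taxonomy. Indices: accession, accession stem
(version-stripped), GI, and (MD5, taxon) compounds for both protein and
DNA hashes. Insert replaces on the accession stem — only the latest
version of an entry is retained, so an obsolete GI or versioned
accession stops resolving, which mirrors how GI codes go stale upstream.
All-digit query tokens are tried as GI first, then as accession.

## Taxonomy

`nodes.dmp`/`names.dmp` load into an in-memory tree (scientific name
from the "scientific name" class; common name from "genbank common
name", falling back to "common name"; synonyms ignored). Each ingested
CDS increments the counter of its *annotated* taxon only — counters
are not propagated to ancestors, and importance comparisons use these
leaf counts; a separate `aggregate_count` query sums a subtree when a
rank-level report wants it. Merged/deleted taxa are not handled;
records whose taxon is absent from the dump keep `taxon_id` but carry
no taxonomy-derived annotation and score importance 0.

## Selection pipeline

Stages: resolve → expand → cluster → flag → represent.

**Resolve.** Identifiers from the input line or FASTA title are tried
in order (accession before GI for `gi|...|ref|...|` headers). If they
fail and a sequence is present, its hash is looked up in the protein
index first, then the DNA index — a fixed order, chosen because
protein input is the common case for the expansion workflows; a
`[Species name]` bracket on the title line restricts hash matches to
that taxon when the name resolves (exact, case-insensitive match on
scientific or common name; unmatched hints disable the restriction
with a warning rather than failing the item). A sequence matching
several records within scope admits *all* of them — expansion
semantics then apply. A sequence matching nothing becomes a
passthrough record: label, sequence, and bracket-derived taxonomy
only. Failures are data (reported), never exceptions.

**Expand.** `full` pulls every record sharing the protein MD5 (all
synonymous CDS and all taxa); `cds_within_taxon` uses the compound
(MD5, taxon) index to add CDS variants without widening taxonomic
coverage. Records arising twice keep their first appearance only.
Taxonomic-only expansion is the documented composition: full expansion
followed by protein-sequence redundancy removal.

**Cluster.** One key per run: accession, protein/DNA MD5, the same
per-taxon (identical sequences in different taxa stay separate), or
`tax_rank:<rank>` — the lineage ancestor at that rank. A record whose
lineage lacks the rank clusters alone under its own taxon rather than
being discarded (information preservation; visible in the report).
Clusters and members keep input order.

**Flag.** Five per-member quality flags: incomplete N-terminus
(= `partial5`), incomplete C-terminus (= `partial3`), ambiguous DNA,
ambiguous protein, length outside a user window. Defaults enforce the
first four; each is individually toggleable, and the length window is
off unless given. Length and ambiguity are evaluated on the *output*
sequence kind (DNA when DNA output is requested), since that is the
sequence whose quality the user will consume. Passthrough records have
unknown provenance, so their completeness flags are false and only
ambiguity is computed.

**Represent.** Among members passing quality control the winner
maximizes, lexicographically: species importance (per-taxon CDS count),
RefSeq membership, store-wide protein representation count (computed at
query time, not precomputed), CDS length, source entry length, and
finally earliest input position. The single tuple comparison is
equivalent to sequential elimination "until one remains" because every
key is totally ordered; a brute-force sort oracle over random ≤8-member
clusters pins the equivalence in tests. If no member passes: best-effort
mode picks the member with the most unambiguous residues in the output
kind (ties → input order); drop mode leaves the cluster unrepresented.

## Label engine

Templates are printf-style dictionary formatting restricted to the
three conversions the label language needs — `%(key)s`, `%(key).Ns`
(truncate), `%(key)M.Nf` (fixed-point float, M-wide field) — rather
than full host-language formatting, keeping templates portable and
total: unknown keys render empty with a warning so one odd record never
aborts a batch; malformed conversions raise with the position.
Guaranteed keys include identifiers (`acv`, `gi`, `taxID`), names
(`SciName`, `ComName` with scientific-name fallback), `genus` and
`species` (the epithet — the binomial minus its genus, so
`>%(genus).1s%(species)s` contracts *Homo sapiens* to `Hsapiens`),
every named rank on the lineage (`order`, `family`, …), `sqNr`,
`pcGC`, `length`, `origLabel`, and `today` (clock-injectable via
`--today` so runs are byte-reproducible).

Finalization maps characters outside `[A-Za-z0-9_.-]` to `_` (strict
mode), truncates to the cap, then appends `_2`, `_3`, … to duplicates
(first occurrence unchanged; the suffix may exceed the cap by its own
width; a literal `x_2` in the input cannot collide — the suffix counter
skips taken names). Output is FASTA wrapped at 60 columns (header =
label + space + comment) or, in no-sequence mode, `label<TAB>comment`
lines — a labeled property file for tree relabeling/annotation tools.

Wobble coding replaces the third base of each codon with R (A/G),
Y (C/T), or N (anything else), leaving positions 1–2 untouched; R and Y
map to themselves so the recoding is idempotent. Whole-sequence R/Y
recoding is a separate mode (`ry`), an extension beyond the
codon-aware one.

## Synthetic data generator

The generator is the test oracle: it writes flat files *and* the
expected parse result per CDS, so ingest tests never re-derive
expectations from the parser under test. Proteins are uniform random
over the 20 standard amino acids; DNA is produced by back-translating
through the standard codon table with a random synonymous codon per
residue plus a stop, so `/translation` genuinely matches the spliced
CDS and complete CDS satisfy `len(dna) == 3·(len(aa)+1)` by
construction. 5′-partial CDS drop their first codon and residue
(keeping frame and translation consistent); 3′-partial CDS lack the
stop. The case grid mixes strands (40% minus), spliced two-exon
locations (40%), partial ends (15% each side), pseudo (10%) and
translation-less (5%) CDS, and ambiguous characters (10% of DNA, 5% of
proteins get one N/X) — rates chosen to exercise every code path many
times in a ~200-CDS corpus while keeping most records clean, roughly
like a curated slice of real data. The toy taxonomy embeds a real
primate lineage (root → Primates → Hominidae → Homo → *Homo sapiens*,
common name "human") plus a second hominid, a rodent and a virus, with
random extra species appended per seed. Same seed, same bytes.

What the generator does **not** emulate: sequence homology and
evolutionary structure (sequences are random, so identity-based
clustering only merges exact duplicates the tests plant deliberately),
multi-interval splicing beyond two exons, `codon_start` offsets > 1,
trans-splicing, and the scale and annotation noise of real GenBank
divisions. Passing tests therefore demonstrate correctness of parsing,
indexing, set algebra and selection logic — not robustness to every
annotation idiosyncrasy in the wild.

## Problem sizes and numerical choices

The test corpus is 90 entries (~220 CDS) and the oracle comparison runs
1,000 random clusters over a 300-record store — sizes at which every
combinatorial case appears repeatedly while the whole suite stays
interactive. GC percent is stored rounded to 2 decimals (the precision
the `%(pcGC)5.2f` idiom prints). Tie-breaks everywhere bottom out in
input order, making every pipeline stage deterministic for a fixed
store; there is no randomness outside the generator.

## Known limitations

* No incremental updates: databases are rebuilt in full.
* No similarity-threshold clustering — redundancy is exact identity or
  taxonomy, by design; use an identity-threshold tool upstream if you
  need 90%-identity clusters.
* ASN.1/XML GenBank, merged taxa (`merged.dmp`), and mixed-strand or
  >2-operator locations are unsupported.
* The annotation-key inventory covers the fields the formatting idioms
  need; a handful of rarely used qualifiers are parsed but not exposed
  as template keys.
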