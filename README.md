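# cdskit

Taxonomy-aware extraction, selection, de-duplication and relabeling of
protein-coding sequences (CDS) from GenBank flat files.

## The problem

Preparing a high-quality sequence data set for phylogenetics or
molecular-evolution work means juggling several chores at once:

* **CDS access.** Protein identifiers map cleanly to amino acid
  sequences, but the *coding DNA* lives inside a longer nucleotide
  entry and has to be spliced out of a `join()`/`complement()` feature
  location.
* **Redundancy control.** Identical entries should collapse to one
  representative — by accession, by protein or DNA sequence identity
  (optionally keeping duplicates that live in different taxa), or by
  taxonomic rank, so that, say, each family contributes one sequence.
* **Quality control.** Partially sequenced entries are only reliably
  detectable from the `<` and `>` markers in the GenBank feature
  location, which flag incomplete 5′ and 3′ ends; ambiguous residues
  and off-length sequences also need filtering — but ideally only when
  a better equivalent exists.
* **Choosing the representative.** An expert picks the best member of
  each redundant cluster by species prominence, RefSeq membership, how
  often the protein is sequenced, and sequence completeness. `cdskit`
  automates exactly that decision, in that order, using the per-taxon
  CDS count as the proxy for how well-studied a species is.
* **Labeling.** Downstream tools choke on long labels, special
  characters and duplicate names; informative labels need taxonomy.

`cdskit` builds a local, indexed store of every annotated CDS (DNA +
protein + annotation + taxonomy) from GenBank flat files and an NCBI
taxdump, then runs a resolve → expand → cluster → flag → represent →
format pipeline over it.

## Core machinery

* Records are indexed by protein accession (versioned and stem), GI,
  and MD5 of the uppercased protein/DNA sequence — plus compound
  (MD5, taxon) indices, so "all entries with this exact sequence,
  in this species" is one lookup. Lookup is case-insensitive but
  otherwise exact; only the latest version of an entry is kept.
* The taxonomy tree (nodes.dmp/names.dmp) carries per-taxon CDS
  counters, incremented during ingest; `species_importance` drives
  representative choice.
* Cluster representatives maximize the tuple *(species importance,
  RefSeq membership, protein representation count, CDS length, source
  entry length, − input position)* over the members that pass quality
  control; if none passes, the member with the most unambiguous
  residues is used (or the cluster is dropped, on request).
* Labels render from per-record annotation dictionaries with
  printf-style `%(keyword)s` templates (`ComName`, `SciName`, `genus`,
  `species`, `acv`, `gi`, `taxID`, `gene`, rank names like `order` and
  `family`, `sqNr`, `pcGC`, `today`, …), then get sanitized, truncated
  and uniquified. Output is FASTA (protein, DNA, or R/Y wobble-recoded
  DNA) or a two-column label/property file for tree-annotation tools.

## Worked example

Everything below runs offline on synthetic data:

```sh
cdskit make-fixtures --seed 5 --out fx --entries 12
cdskit build --genbank fx/fixture.gb --taxdump fx --db cds.db
```

```
entries read: 12
CDS kept: 20
pseudo skipped: 1
no-translation skipped: 1
entries without sequence: 0
```

Select four proteins by accession and emit relabeled protein FASTA:

```sh
cdskit select --db cds.db --in ids.txt --require none --seq aa \
    --label '>%(SciName)s_%(gene)s' --comment '%(acv)s gc=%(pcGC)5.2f' \
    --strict-chars --today 2013-05-10
```

```
>Homo_synthetica8_gene1 NP_000001.1 gc=48.72
MWHNSHXWTANI
>Homo_synthetica6_gene3 AAB00003.1 gc=45.45
MWFQGMIVWAWPHMPTRAPTVFIVNKGFGFPDCACSCEVENYCCVIQIWLDSDW
>Mus_synthetica5_gene8 NP_000008.1 gc=49.65
NNLWIGDFWVRCEDVCNNRPKTIQWWQMRPVVYICDQTPEYTRMWYG
>Gorilla_gorilla_gene10 AAB00010.1 gc=46.30
MVFLRGAIAGEFLQWVQDNDKVIKQNHVMKNEPYL
```

Labels are the sanitized species + gene name; comments carry the
versioned accession and the CDS GC percentage. The run report goes to
stderr:

```
items: 4  resolved: 4  unresolved: 0  passthrough: 0
expanded records: 4  clusters: 4  dropped: 0  output: 4
```

The same selection as third-codon-position R/Y wobble-recoded DNA
(purine → R, pyrimidine → Y), useful for saturation-aware phylogenetics:

```sh
cdskit select --db cds.db --in ids.txt --require none --seq wobble --label '>%(acv)s'
```

```
>NP_000001.1
ATRTGRCAYANYAGYCAYACRTGRACYGCYAAYATRTGR
>AAB00003.1
ATRTGRTTYCARGGRATRATYGTRTGRGCYTGRCCRCAYATRCCRACYAGRGCYCCRACR
```

With `--seq none` the label/comment pair becomes one tab-separated line
per sequence — a labeled property file for relabeling or annotating
phylogenetic trees.

Selections can also be FASTA: identifiers on NCBI-style title lines are
tried first, then the sequence itself is matched by hash, restricted to
the species named in square brackets (`[Homo sapiens]`) when present;
unmatched sequences pass through with the bracket-derived taxonomy
attached.

As a library:

```python
from cdskit import CDSStore, PipelineConfig, parse_selection, run

store = CDSStore("cds.db")
taxonomy = store.load_taxonomy()
cfg = PipelineConfig(expansion="full", redundancy_key="dna_seq")
records, report = run(parse_selection("NP_000001.1"), cfg, store, taxonomy)
```

yields the complete-but-non-redundant set of CDS variants coding for
that protein, across all taxa.

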