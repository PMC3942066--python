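"""Persistent, indexed CDS store backed by a single sqlite3 file.

The index set mirrors what fast sequence selection needs: protein
accession (versioned and unversioned stem), GI, protein/DNA MD5, and the
compound (MD5, taxon) pairs that let sequence lookups be restricted to a
species.  Re-inserting a record whose accession stem matches an existing
one replaces it — only the latest version of an entry is kept.

The store also persists the taxonomy tree (with its CDS counters) so a
built database is self-contained for later selection runs.
"""

from __future__ import annotations

import json
import sqlite3
from datetime import date
from typing import IO, Iterable, Iterator, Optional

from cdskit.genbank import CDSRecord, FeatureLocation, IngestReport, parse_genbank
from cdskit.taxonomy import TaxonNode, TaxonomyDB, load_taxdump

_SCHEMA = """
CREATE TABLE IF NOT EXISTS cds (
    rowid INTEGER PRIMARY KEY,
    accession TEXT NOT NULL,
    stem TEXT NOT NULL,
    gi INTEGER,
    taxon_id INTEGER,
    prot_md5 TEXT NOT NULL,
    dna_md5 TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE UNIQUE INDEX IF NOT EXISTS idx_stem ON cds(stem);
CREATE INDEX IF NOT EXISTS idx_accession ON cds(accession);
CREATE INDEX IF NOT EXISTS idx_gi ON cds(gi);
CREATE INDEX IF NOT EXISTS idx_prot_md5 ON cds(prot_md5, taxon_id);
CREATE INDEX IF NOT EXISTS idx_dna_md5 ON cds(dna_md5, taxon_id);
CREATE TABLE IF NOT EXISTS taxon (
    tax_id INTEGER PRIMARY KEY,
    parent_id INTEGER NOT NULL,
    rank TEXT NOT NULL,
    scientific_name TEXT NOT NULL,
    common_name TEXT,
    cds_count INTEGER NOT NULL
);
"""


def accession_stem(accession: str) -> str:
    """Accession with a trailing ``.N`` version suffix removed."""
    head, dot, tail = accession.rpartition(".")
    if dot and tail.isdigit():
        return head
    return accession


def _record_to_json(record: CDSRecord) -> str:
    d = dict(record.__dict__)
    loc = d.pop("location")
    d["location"] = (
        {
            "intervals": loc.intervals,
            "left_open": loc.left_open,
            "right_open": loc.right_open,
        }
        if loc is not None
        else None
    )
    ed = d.pop("entry_date")
    d["entry_date"] = ed.isoformat() if ed is not None else None
    return json.dumps(d, separators=(",", ":"))


def _record_from_json(payload: str) -> CDSRecord:
    d = json.loads(payload)
    loc = d.pop("location")
    location = (
        FeatureLocation(
            intervals=[tuple(iv) for iv in loc["intervals"]],
            left_open=loc["left_open"],
            right_open=loc["right_open"],
        )
        if loc is not None
        else None
    )
    ed = d.pop("entry_date")
    entry_date = date.fromisoformat(ed) if ed else None
    return CDSRecord(location=location, entry_date=entry_date, **d)


class CDSStore:
    """Exact-match CDS retrieval over the sqlite index set."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "CDSStore":
        return self

    def __exit__(self, *exc) -> None:
        self.conn.commit()
        self.close()

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM cds").fetchone()[0]

    def __iter__(self) -> Iterator[CDSRecord]:
        for (payload,) in self.conn.execute("SELECT payload FROM cds ORDER BY rowid"):
            yield _record_from_json(payload)

    # -- writes -------------------------------------------------------

    def put(self, record: CDSRecord) -> int:
        """Insert a record; a matching accession stem replaces (latest wins)."""
        stem = accession_stem(record.protein_accession)
        cur = self.conn.execute(
            """INSERT INTO cds (accession, stem, gi, taxon_id, prot_md5, dna_md5, payload)
               VALUES (?,?,?,?,?,?,?)
               ON CONFLICT(stem) DO UPDATE SET
                 accession=excluded.accession, gi=excluded.gi,
                 taxon_id=excluded.taxon_id, prot_md5=excluded.prot_md5,
                 dna_md5=excluded.dna_md5, payload=excluded.payload""",
            (
                record.protein_accession,
                stem,
                record.gi,
                record.taxon_id,
                record.prot_md5,
                record.dna_md5,
                _record_to_json(record),
            ),
        )
        return cur.lastrowid

    def commit(self) -> None:
        self.conn.commit()

    # -- reads --------------------------------------------------------

    def _one(self, sql: str, args: tuple) -> Optional[CDSRecord]:
        row = self.conn.execute(sql, args).fetchone()
        return _record_from_json(row[0]) if row else None

    def get_by_id(self, identifier: str) -> Optional[CDSRecord]:
        """Look up by accession (versioned or not) or GI.

        A versioned accession must match exactly; an unversioned one
        matches the stored latest version; an all-digit token is tried
        as a GI first, then as an accession.
        """
        identifier = identifier.strip()
        if not identifier:
            return None
        if identifier.isdigit():
            rec = self._one(
                "SELECT payload FROM cds WHERE gi = ?", (int(identifier),)
            )
            if rec is not None:
                return rec
        rec = self._one(
            "SELECT payload FROM cds WHERE accession = ?", (identifier,)
        )
        if rec is not None:
            return rec
        # unversioned: match the stem of whatever version is stored
        return self._one("SELECT payload FROM cds WHERE stem = ?", (identifier,))

    def get_by_hash(
        self, md5: str, kind: str, taxon_id: Optional[int] = None
    ) -> list[CDSRecord]:
        """All records sharing an MD5, optionally restricted to one taxon."""
        if kind not in ("protein", "dna"):
            raise ValueError(f"kind must be 'protein' or 'dna', got {kind!r}")
        col = "prot_md5" if kind == "protein" else "dna_md5"
        if taxon_id is None:
            rows = self.conn.execute(
                f"SELECT payload FROM cds WHERE {col} = ? ORDER BY rowid", (md5,)
            )
        else:
            rows = self.conn.execute(
                f"SELECT payload FROM cds WHERE {col} = ? AND taxon_id = ? ORDER BY rowid",
                (md5, taxon_id),
            )
        return [_record_from_json(p) for (p,) in rows]

    def count_by_protein_hash(self, prot_md5: str) -> int:
        """Store-wide representation count of a protein sequence."""
        return self.conn.execute(
            "SELECT COUNT(*) FROM cds WHERE prot_md5 = ?", (prot_md5,)
        ).fetchone()[0]

    # -- taxonomy persistence ----------------------------------------

    def save_taxonomy(self, taxonomy: TaxonomyDB) -> None:
        self.conn.execute("DELETE FROM taxon")
        self.conn.executemany(
            "INSERT INTO taxon VALUES (?,?,?,?,?,?)",
            (
                (
                    n.tax_id,
                    n.parent_id,
                    n.rank,
                    n.scientific_name,
                    n.common_name,
                    n.cds_count,
                )
                for n in taxonomy.nodes.values()
            ),
        )
        self.conn.commit()

    def has_taxonomy(self) -> bool:
        return (
            self.conn.execute("SELECT COUNT(*) FROM taxon").fetchone()[0] > 0
        )

    def load_taxonomy(self) -> TaxonomyDB:
        db = TaxonomyDB()
        for tax_id, parent_id, rank, sci, com, count in self.conn.execute(
            "SELECT * FROM taxon"
        ):
            db.add_node(
                TaxonNode(
                    tax_id=tax_id,
                    parent_id=parent_id,
                    rank=rank,
                    scientific_name=sci,
                    common_name=com,
                    cds_count=count,
                )
            )
        db.link()
        return db


def build_database(
    genbank_streams: Iterable[IO[str]],
    nodes_stream: IO[str],
    names_stream: IO[str],
    path: str = ":memory:",
) -> tuple[CDSStore, TaxonomyDB, IngestReport]:
    """One-shot database build: taxonomy + CDS ingest + counters.

    Parses every GenBank stream, stores each kept CDS, increments the
    CDS counter of its annotated taxon, and persists the taxonomy
    (counters included) into the same database file.
    """
    taxonomy = load_taxdump(nodes_stream, names_stream)
    store = CDSStore(path)
    report = IngestReport()
    for stream in genbank_streams:
        for record in parse_genbank(stream, report):
            store.put(record)
            taxonomy.count_cds(record.taxon_id)
    store.save_taxonomy(taxonomy)
    store.commit()
    return store, taxonomy, report
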