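"""Single-file SQLite persistence of a guide database.

Two core tables mirror the gid-keyed design: ``guides`` + ``sites``
(jointly the main table: one row per guide occurrence with sequence,
coordinates, flanks, GC, scores and annotations) and ``mismatch`` (the
0..k neighborhood graph keyed by gid).  ``te_copies`` and ``elements``
persist the annotation layers so design queries can run from the database
alone, and ``metadata`` records build parameters for provenance.

Rebuilding from identical inputs and parameters is bit-identical except
for the metadata timestamp.
"""

from __future__ import annotations

import datetime
import json
import logging
import sqlite3
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import __version__
from .annotation import (ElementAnnotation, TEAnnotation, TECopy,
                         classify_site)
from .design import DesignConfig
from .index import GuideIndex
from .scan import GuideSite
from .scoring import (MismatchPenaltyTable, ScoreModel,
                      default_mismatch_penalties, default_on_target_model,
                      site_penalty, specificity_score)

log = logging.getLogger(__name__)

SCHEMA = """
CREATE TABLE guides (
    gid INTEGER PRIMARY KEY,
    protospacer TEXT NOT NULL UNIQUE,
    gc REAL NOT NULL,
    on_target REAL,
    specificity REAL
);
CREATE TABLE sites (
    gid INTEGER NOT NULL REFERENCES guides(gid),
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    pam TEXT NOT NULL,
    upstream6 TEXT NOT NULL,
    downstream6 TEXT NOT NULL,
    on_target REAL,
    element_class TEXT NOT NULL,
    te_subfamily TEXT,
    te_copy_id TEXT,
    PRIMARY KEY (chrom, start, strand)
);
CREATE INDEX sites_gid ON sites(gid);
CREATE TABLE mismatch (
    gid INTEGER NOT NULL REFERENCES guides(gid),
    neighbor_gid INTEGER NOT NULL REFERENCES guides(gid),
    mismatches INTEGER NOT NULL,
    PRIMARY KEY (gid, neighbor_gid)
);
CREATE TABLE te_copies (
    copy_id TEXT PRIMARY KEY,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    subfamily TEXT NOT NULL,
    family TEXT NOT NULL,
    te_class TEXT NOT NULL
);
CREATE TABLE elements (
    kind TEXT NOT NULL,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
CREATE TABLE metadata (
    key TEXT PRIMARY KEY,
    value TEXT
);
"""


def write_db(path: str | Path, index: GuideIndex, tes: TEAnnotation,
             elements: ElementAnnotation,
             cfg: Optional[DesignConfig] = None, *,
             score_model: Optional[ScoreModel] = None,
             penalty_table: Optional[MismatchPenaltyTable] = None,
             metadata: Optional[Dict[str, str]] = None) -> "GuideDatabase":
    """Build and write the guide database; returns it opened.

    Per-site on-target scores use ``score_model`` (bundled default if
    None); per-guide specificity aggregates mismatch-neighborhood
    penalties from ``penalty_table``.  Referential integrity of the
    mismatch table is verified before commit.
    """
    cfg = cfg or DesignConfig()
    score_model = score_model or default_on_target_model()
    penalty_table = penalty_table or default_mismatch_penalties()
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    conn.executescript(SCHEMA)

    mismatch_rows: List[Tuple[int, int, int]] = []
    for rec in index.records:
        penalties: List[float] = []
        neighbor_rows: List[Tuple[int, int, int]] = []
        for nproto, ngid, mm in index.query(rec.protospacer, cfg.k_max):
            neighbor_rows.append((rec.gid, ngid, mm))
            if ngid != rec.gid:
                p = site_penalty(penalty_table, rec.protospacer, nproto)
                penalties.extend([p] * len(index.record(ngid).sites))
        spec = specificity_score(penalties)
        first_ctx = rec.sites[0].context30() if rec.sites else None
        on_target = score_model.score(first_ctx) if first_ctx else None
        conn.execute("INSERT INTO guides VALUES (?,?,?,?,?)",
                     (rec.gid, rec.protospacer, rec.gc, on_target, spec))
        for site in rec.sites:
            element, te_hit = classify_site(site, elements, tes)
            site_score = score_model.score(site.context30())
            conn.execute(
                "INSERT INTO sites VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
                (rec.gid, site.chrom, site.start, site.end, site.strand,
                 site.pam, site.upstream6, site.downstream6, site_score,
                 element, te_hit[0] if te_hit else None,
                 te_hit[1] if te_hit else None))
        mismatch_rows.extend(neighbor_rows)

    # neighbor gids can exceed the current gid, so the mismatch table is
    # filled only once every guide row exists
    conn.executemany("INSERT INTO mismatch VALUES (?,?,?)", mismatch_rows)
    n_mismatch = len(mismatch_rows)

    for c in sorted(tes.copies, key=lambda c: c.copy_id):
        conn.execute("INSERT INTO te_copies VALUES (?,?,?,?,?,?,?,?)",
                     (c.copy_id, c.chrom, c.start, c.end, c.strand,
                      c.subfamily, c.family, c.te_class))
    for kind, chrom, start, end in elements.intervals():
        conn.execute("INSERT INTO elements VALUES (?,?,?,?)",
                     (kind, chrom, start, end))

    meta = {
        "teguide_version": __version__,
        "design_config": json.dumps(asdict(cfg), sort_keys=True),
        "n_guides": str(len(index)),
        "n_sites": str(sum(len(r.sites) for r in index.records)),
        "n_mismatch_rows": str(n_mismatch),
        "created_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    meta.update(metadata or {})
    conn.executemany("INSERT OR REPLACE INTO metadata VALUES (?,?)",
                     sorted(meta.items()))

    orphans = conn.execute(
        "SELECT COUNT(*) FROM mismatch WHERE gid NOT IN (SELECT gid FROM guides)"
        " OR neighbor_gid NOT IN (SELECT gid FROM guides)").fetchone()[0]
    if orphans:
        conn.close()
        path.unlink()
        raise sqlite3.IntegrityError(
            f"{orphans} mismatch rows reference unknown gids")
    conn.commit()
    log.info("wrote %s: %s guides, %s sites, %s mismatch rows",
             path, meta["n_guides"], meta["n_sites"], meta["n_mismatch_rows"])
    return GuideDatabase(path, conn)


class GuideDatabase:
    """Read interface over a written guide database."""

    def __init__(self, path: str | Path, conn: Optional[sqlite3.Connection] = None):
        self.path = Path(path)
        if conn is None and not self.path.exists():
            raise FileNotFoundError(self.path)
        self.conn = conn or sqlite3.connect(self.path)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "GuideDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- reconstruction of in-memory objects -----------------------------

    def metadata(self) -> Dict[str, str]:
        return dict(self.conn.execute("SELECT key, value FROM metadata"))

    def load_index(self) -> GuideIndex:
        sites_by_gid: Dict[int, List[GuideSite]] = {}
        for row in self.conn.execute(
                "SELECT gid, chrom, start, end, strand, pam, upstream6,"
                " downstream6 FROM sites ORDER BY gid, chrom, start, strand"):
            gid, chrom, start, end, strand, pam, up, down = row
            sites_by_gid.setdefault(gid, []).append(
                (chrom, start, end, strand, pam, up, down))
        all_sites: List[GuideSite] = []
        for gid, proto in self.conn.execute(
                "SELECT gid, protospacer FROM guides ORDER BY gid"):
            for chrom, start, end, strand, pam, up, down in sites_by_gid.get(gid, []):
                all_sites.append(GuideSite(chrom, start, end, strand, proto,
                                           pam, up, down))
        index = GuideIndex.from_sites(all_sites)
        for gid, on_target, spec in self.conn.execute(
                "SELECT gid, on_target, specificity FROM guides"):
            rec = index.record(gid)
            rec.on_target, rec.specificity = on_target, spec
        return index

    def load_te_annotation(self) -> TEAnnotation:
        copies = [TECopy(chrom, start, end, strand, subfamily, family,
                         te_class, copy_id)
                  for copy_id, chrom, start, end, strand, subfamily, family,
                  te_class in self.conn.execute(
                      "SELECT copy_id, chrom, start, end, strand, subfamily,"
                      " family, te_class FROM te_copies")]
        return TEAnnotation(copies)

    def load_elements(self) -> ElementAnnotation:
        rows = self.conn.execute("SELECT kind, chrom, start, end FROM elements")
        return ElementAnnotation.from_intervals(rows)

    # -- query patterns ---------------------------------------------------

    def query_copy(self, copy_id: str) -> Optional[Tuple[TECopy, List[tuple]]]:
        """Coordinates of a TE copy plus the guide occurrences fully
        contained in it; None for an unknown id."""
        row = self.conn.execute(
            "SELECT copy_id, chrom, start, end, strand, subfamily, family,"
            " te_class FROM te_copies WHERE copy_id = ?", (copy_id,)).fetchone()
        if row is None:
            return None
        copy = TECopy(row[1], row[2], row[3], row[4], row[5], row[6],
                      row[7], row[0])
        guides = self.conn.execute(
            "SELECT s.gid, g.protospacer, s.chrom, s.start, s.end, s.strand"
            " FROM sites s JOIN guides g USING (gid)"
            " WHERE s.chrom = ? AND s.start >= ? AND s.end <= ?"
            " ORDER BY s.start, s.strand, s.gid",
            (copy.chrom, copy.start, copy.end)).fetchall()
        return copy, guides

    def query_subfamily(self, subfamily: str) -> List[TECopy]:
        return [TECopy(chrom, start, end, strand, subfamily, family,
                       te_class, copy_id)
                for copy_id, chrom, start, end, strand, family, te_class
                in self.conn.execute(
                    "SELECT copy_id, chrom, start, end, strand, family,"
                    " te_class FROM te_copies WHERE subfamily = ?"
                    " ORDER BY chrom, start", (subfamily,))]

    def query_interval(self, chrom: str, start: int, end: int
                       ) -> Tuple[List[TECopy], List[tuple]]:
        """TE copies and guide occurrences overlapping a 0-based half-open
        interval."""
        copies = [TECopy(c, s, e, strand, subfamily, family, te_class, copy_id)
                  for copy_id, c, s, e, strand, subfamily, family, te_class
                  in self.conn.execute(
                      "SELECT copy_id, chrom, start, end, strand, subfamily,"
                      " family, te_class FROM te_copies"
                      " WHERE chrom = ? AND start < ? AND end > ?"
                      " ORDER BY start", (chrom, end, start))]
        guides = self.conn.execute(
            "SELECT s.gid, g.protospacer, s.chrom, s.start, s.end, s.strand"
            " FROM sites s JOIN guides g USING (gid)"
            " WHERE s.chrom = ? AND s.start < ? AND s.end > ?"
            " ORDER BY s.start, s.strand, s.gid",
            (chrom, end, start)).fetchall()
        return copies, guides

    # -- dumps ------------------------------------------------------------

    def dump_main_csv(self, path: str | Path) -> int:
        """The spec'd main table — one row per (gid, occurrence) — as CSV.
        Coordinates are printed 1-based inclusive (browser convention)."""
        import pandas as pd
        df = pd.read_sql_query(
            "SELECT s.gid, g.protospacer, s.chrom, s.start + 1 AS start,"
            " s.end AS end, s.strand, s.pam, s.upstream6, s.downstream6,"
            " g.gc, s.on_target, g.specificity, s.element_class,"
            " s.te_subfamily, s.te_copy_id"
            " FROM sites s JOIN guides g USING (gid)"
            " ORDER BY s.gid, s.chrom, s.start, s.strand", self.conn)
        df.to_csv(path, index=False)
        return len(df)

    def dump_mismatch_csv(self, path: str | Path) -> int:
        import pandas as pd
        df = pd.read_sql_query(
            "SELECT gid, neighbor_gid, mismatches FROM mismatch"
            " ORDER BY gid, neighbor_gid", self.conn)
        df.to_csv(path, index=False)
        return len(df)


def query_te(db: GuideDatabase, *, copy_id: Optional[str] = None,
             subfamily: Optional[str] = None,
             interval: Optional[Tuple[str, int, int]] = None):
    """Dispatch the three offline query patterns: copy_id -> coordinates +
    contained guides; subfamily -> its copies; interval -> overlapping TE
    copies and guides.  Unknown keys give empty results, never a crash."""
    if copy_id is not None:
        return db.query_copy(copy_id)
    if subfamily is not None:
        return db.query_subfamily(subfamily)
    if interval is not None:
        return db.query_interval(*interval)
    raise ValueError("one of copy_id, subfamily or interval is required")
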