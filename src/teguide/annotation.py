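"""TE and gene-model annotation of guide sites.

Two annotation layers are maintained:

* transposable-element copies parsed from RepeatMasker ``.out`` (each
  genomic instance gets a genome-wide unique copy id of the form
  ``<subfamily>_dup<i>``, with ``i`` the 1-based rank of the copy among
  its subfamily ordered by (chromosome, start));
* a genetic-element map built from a GTF/GFF gene model, classifying every
  position as promoter-TSS, exon, intron or intergenic.

A guide site *targets* a TE copy only when its whole 23-bp interval is
contained in the copy (the smallest containing copy wins when copies are
nested).  Its element class is decided by any overlap of the 23-bp
interval under the precedence promoter-TSS > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gffutils
from intervaltree import IntervalTree

from .scan import GuideSite

PROMOTER = "promoter-TSS"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"
ELEMENT_CLASSES = (PROMOTER, EXON, INTRON, INTERGENIC)


@dataclass(frozen=True)
class TECopy:
    """One annotated genomic instance of a TE subfamily."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    te_class: str
    copy_id: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


def assign_copy_ids(raw: Sequence[tuple], chrom_order: Optional[Sequence[str]] = None
                    ) -> List[TECopy]:
    """Build TECopy objects from (chrom, start, end, strand, subfamily,
    family, te_class) tuples, assigning ``<subfamily>_dup<i>`` ids ordered
    by (chromosome rank, start).  ``chrom_order`` defaults to order of
    first appearance."""
    if chrom_order is None:
        seen: list[str] = []
        for row in raw:
            if row[0] not in seen:
                seen.append(row[0])
        chrom_order = seen
    rank = {c: i for i, c in enumerate(chrom_order)}
    ordered = sorted(raw, key=lambda r: (rank.get(r[0], len(rank)), r[1], r[2]))
    counters: Dict[str, int] = {}
    copies = []
    for chrom, start, end, strand, subfamily, family, te_class in ordered:
        counters[subfamily] = counters.get(subfamily, 0) + 1
        copies.append(TECopy(chrom, start, end, strand, subfamily, family,
                             te_class, f"{subfamily}_dup{counters[subfamily]}"))
    return copies


def parse_repeatmasker(path: str | Path,
                       chrom_order: Optional[Sequence[str]] = None) -> List[TECopy]:
    """Parse a RepeatMasker ``.out`` annotation into TECopy records.

    Expects the standard layout (header lines, then whitespace-delimited
    columns: score, %div, %del, %ins, query, begin, end, (left), strand,
    repeat name, class/family, ...).  Coordinates are converted from
    1-based inclusive to 0-based half-open; strand code ``C`` maps to
    ``-``.  Malformed rows raise ValueError naming the line number.
    """
    raw: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].lstrip("-").isdigit():
                if lineno <= 3:  # the .out banner spans the first 3 lines
                    continue
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 columns, got {len(fields)}")
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            strand_code = fields[8]
            if strand_code in ("+",):
                strand = "+"
            elif strand_code in ("C", "-"):
                strand = "-"
            else:
                raise ValueError(
                    f"{path}: line {lineno}: unknown strand code {strand_code!r}")
            subfamily = fields[9]
            cls_fam = fields[10].split("/", 1)
            te_class = cls_fam[0]
            family = cls_fam[1] if len(cls_fam) == 2 else cls_fam[0]
            if begin < 1 or end < begin:
                raise ValueError(f"{path}: line {lineno}: bad interval {begin}-{end}")
            raw.append((chrom, begin - 1, end, strand, subfamily, family, te_class))
    return assign_copy_ids(raw, chrom_order)


class TEAnnotation:
    """Interval-indexed collection of TE copies."""

    def __init__(self, copies: Iterable[TECopy]):
        self.copies: List[TECopy] = list(copies)
        self.by_id: Dict[str, TECopy] = {}
        self._by_subfamily: Dict[str, List[TECopy]] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for c in self.copies:
            if c.copy_id in self.by_id:
                raise ValueError(f"duplicate copy_id {c.copy_id}")
            self.by_id[c.copy_id] = c
            self._by_subfamily.setdefault(c.subfamily, []).append(c)
            self._trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c)

    @property
    def subfamilies(self) -> List[str]:
        return sorted(self._by_subfamily)

    def copies_of(self, subfamily: str) -> List[TECopy]:
        return list(self._by_subfamily.get(subfamily, []))

    def overlapping(self, chrom: str, start: int, end: int) -> List[TECopy]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda c: (c.start, c.end, c.copy_id))

    def containing(self, chrom: str, start: int, end: int) -> List[TECopy]:
        return [c for c in self.overlapping(chrom, start, end)
                if c.contains(chrom, start, end)]

    def smallest_containing(self, chrom: str, start: int, end: int
                            ) -> Optional[TECopy]:
        hits = self.containing(chrom, start, end)
        if not hits:
            return None
        return min(hits, key=lambda c: (c.length, c.copy_id))


class ElementAnnotation:
    """Total classification of genomic positions into genetic elements.

    Holds interval trees for promoters, exons and transcript spans; the
    class of an interval is decided by any overlap with precedence
    promoter-TSS > exon > intron (inside a transcript span but not
    exonic) > intergenic (everything else).
    """

    def __init__(self,
                 promoters: Iterable[Tuple[str, int, int]] = (),
                 exons: Iterable[Tuple[str, int, int]] = (),
                 transcripts: Iterable[Tuple[str, int, int]] = ()):
        self._layers: Dict[str, Dict[str, IntervalTree]] = {
            PROMOTER: {}, EXON: {}, "transcript": {}}
        for layer, rows in ((PROMOTER, promoters), (EXON, exons),
                            ("transcript", transcripts)):
            for chrom, start, end in rows:
                if start < end:
                    self._layers[layer].setdefault(chrom, IntervalTree()
                                                   ).addi(start, end)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Tuple[str, str, Sequence[Tuple[int, int]]]],
                         promoter_window: Tuple[int, int] = (1000, 100)
                         ) -> "ElementAnnotation":
        """Build from (chrom, strand, [(exon_start, exon_end), ...]) rows.

        The TSS is the strand-aware 5' boundary of the transcript span;
        the promoter covers ``[TSS - upstream, TSS + downstream)`` in the
        transcript's own orientation, clamped at position 0.
        """
        up, down = promoter_window
        promoters, exons, spans = [], [], []
        for chrom, strand, exon_list in transcripts:
            exon_list = sorted(exon_list)
            span_start = exon_list[0][0]
            span_end = max(e for _, e in exon_list)
            spans.append((chrom, span_start, span_end))
            exons.extend((chrom, s, e) for s, e in exon_list)
            if strand == "-":
                promoters.append((chrom, max(0, span_end - down), span_end + up))
            else:
                promoters.append((chrom, max(0, span_start - up), span_start + down))
        return cls(promoters, exons, spans)

    def classify(self, chrom: str, start: int, end: int) -> str:
        """Element class of an interval under the overlap-precedence rule."""
        for layer, label in ((PROMOTER, PROMOTER), (EXON, EXON),
                             ("transcript", INTRON)):
            tree = self._layers[layer].get(chrom)
            if tree is not None and tree.overlap(start, end):
                return label
        return INTERGENIC

    def intervals(self) -> Iterator[Tuple[str, str, int, int]]:
        """Yield (kind, chrom, start, end) rows for serialization, where
        kind is 'promoter-TSS', 'exon' or 'transcript'."""
        for layer in (PROMOTER, EXON, "transcript"):
            for chrom in sorted(self._layers[layer]):
                for iv in sorted(self._layers[layer][chrom]):
                    yield layer, chrom, iv.begin, iv.end

    @classmethod
    def from_intervals(cls, rows: Iterable[Tuple[str, str, int, int]]
                       ) -> "ElementAnnotation":
        grouped: Dict[str, list] = {PROMOTER: [], EXON: [], "transcript": []}
        for kind, chrom, start, end in rows:
            grouped[kind].append((chrom, start, end))
        return cls(grouped[PROMOTER], grouped[EXON], grouped["transcript"])


def build_element_map(gtf_path: str | Path,
                      promoter_window: Tuple[int, int] = (1000, 100)
                      ) -> ElementAnnotation:
    """Build the genetic-element map from a GTF/GFF3 gene model.

    Exons are grouped by transcript_id; the transcript span is the hull of
    its exons and the TSS its strand-aware 5' end.  A GTF with no exon
    features is an error.
    """
    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    grouped: Dict[str, Tuple[str, str, list]] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [None])[0]
        if tid is None:
            tid = f"{exon.seqid}:{exon.start}-{exon.end}"
        entry = grouped.setdefault(tid, (exon.seqid, exon.strand, []))
        entry[2].append((exon.start - 1, exon.end))
    if not grouped:
        raise ValueError(f"{gtf_path}: GTF contains no exon features")
    return ElementAnnotation.from_transcripts(grouped.values(), promoter_window)


def classify_site(site: GuideSite, elements: ElementAnnotation,
                  tes: TEAnnotation
                  ) -> Tuple[str, Optional[Tuple[str, str]]]:
    """Annotate one guide occurrence.

    Returns (element_class, te_hit) where te_hit is (subfamily, copy_id)
    of the smallest TE copy fully containing the 23-bp site, or None.
    """
    element = elements.classify(site.chrom, site.start, site.end)
    copy = tes.smallest_containing(site.chrom, site.start, site.end)
    te_hit = (copy.subfamily, copy.copy_id) if copy else None
    return element, te_hit
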