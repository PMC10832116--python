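"""Trie-based index of unique protospacers with budgeted-mismatch search.

All distinct 20-nt protospacers from a genome scan are stored in a prefix
tree.  A query walks the trie depth-first carrying a running mismatch
budget, pruning any branch whose accumulated Hamming distance exceeds the
allowance — this returns exactly the stored words within Hamming distance
``k`` (substitutions only; the index is built exclusively from PAM-bearing
sites, so a near-match without its own NGG is invisible by construction).

Guide identifiers (gids) are assigned in lexicographic order of the
protospacer, starting at 0, so rebuilding from the same genome yields the
same ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, NamedTuple, Optional, Tuple

from .scan import PROTOSPACER_LEN, GuideSite, gc_content

MAX_MISMATCHES = 3


@dataclass
class GuideRecord:
    """A unique protospacer aggregating all of its genomic occurrences."""

    gid: int
    protospacer: str
    sites: List[GuideSite]
    gc: float
    on_target: Optional[float] = None
    specificity: Optional[float] = None


class MismatchNeighbor(NamedTuple):
    """One edge of the 0..k mismatch graph between stored guides."""

    gid: int
    neighbor_gid: int
    mismatches: int


def _validate_query(seq: str, k: int) -> str:
    if not 0 <= k <= MAX_MISMATCHES:
        raise ValueError(f"k must be in 0..{MAX_MISMATCHES}, got {k}")
    seq = seq.upper()
    if len(seq) != PROTOSPACER_LEN or any(ch not in "ACGT" for ch in seq):
        raise ValueError(f"query must be a {PROTOSPACER_LEN}-nt ACGT string")
    return seq


class GuideIndex:
    """Deduplicated protospacer trie supporting Hamming-neighborhood queries."""

    def __init__(self) -> None:
        self._root: dict = {}
        self.records: List[GuideRecord] = []
        self._gid_of: dict[str, int] = {}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_sites(cls, sites: Iterable[GuideSite]) -> "GuideIndex":
        by_proto: dict[str, dict] = {}
        for site in sites:
            occ = by_proto.setdefault(site.protospacer, {})
            occ.setdefault(site.key(), site)  # dedup identical occurrences
        index = cls()
        for gid, proto in enumerate(sorted(by_proto)):
            occurrences = list(by_proto[proto].values())
            index.records.append(
                GuideRecord(gid, proto, occurrences, gc_content(proto))
            )
            index._gid_of[proto] = gid
            node = index._root
            for ch in proto[:-1]:
                node = node.setdefault(ch, {})
            node[proto[-1]] = gid
        return index

    # -- lookup ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protospacer: str) -> bool:
        return protospacer in self._gid_of

    def gid_of(self, protospacer: str) -> int:
        return self._gid_of[protospacer]

    def record(self, gid: int) -> GuideRecord:
        return self.records[gid]

    @property
    def protospacers(self) -> List[str]:
        return [r.protospacer for r in self.records]

    def query(self, seq: str, k: int) -> List[Tuple[str, int, int]]:
        """Stored protospacers within Hamming distance ``k`` of ``seq``.

        Returns (protospacer, gid, mismatches) tuples sorted by
        (mismatches, protospacer).  Branch-and-bound over the trie: a
        partial path is abandoned as soon as its mismatch count exceeds k.
        """
        seq = _validate_query(seq, k)
        last = PROTOSPACER_LEN - 1
        hits: list[tuple[int, int]] = []
        stack: list[tuple[dict, int, int]] = [(self._root, 0, 0)]
        while stack:
            node, depth, mm = stack.pop()
            target = seq[depth]
            if depth == last:
                for ch, gid in node.items():
                    m = mm + (ch != target)
                    if m <= k:
                        hits.append((m, gid))
            else:
                for ch, child in node.items():
                    m = mm + (ch != target)
                    if m <= k:
                        stack.append((child, depth + 1, m))
        out = [(self.records[gid].protospacer, gid, m) for m, gid in hits]
        out.sort(key=lambda t: (t[2], t[0]))
        return out


def build_index(sites: Iterable[GuideSite]) -> GuideIndex:
    """Build a :class:`GuideIndex` from a stream of scanned sites."""
    return GuideIndex.from_sites(sites)


def query_mismatch(index: GuideIndex, seq: str, k: int) -> List[Tuple[str, int, int]]:
    """Stored words within Hamming distance ``k`` of ``seq`` (see
    :meth:`GuideIndex.query`)."""
    return index.query(seq, k)


def neighborhood_table(index: GuideIndex, k_max: int = MAX_MISMATCHES
                       ) -> Iterator[MismatchNeighbor]:
    """Stream every (gid, neighbor_gid, mismatches) pair at distance
    <= k_max, including the distance-0 self pair for every gid.

    The stream is the symmetric closure by construction: each gid's full
    neighborhood is emitted, so (a, b, m) appears iff (b, a, m) does.
    """
    if not 0 <= k_max <= MAX_MISMATCHES:
        raise ValueError(f"k_max must be in 0..{MAX_MISMATCHES}, got {k_max}")
    for rec in index.records:
        for _, ngid, mm in index.query(rec.protospacer, k_max):
            yield MismatchNeighbor(rec.gid, ngid, mm)


def write_mismatch_tsv(index: GuideIndex, handle: IO[str],
                       k_max: int = MAX_MISMATCHES) -> int:
    """Serialize the neighborhood table as TSV (gid, neighbor_gid,
    mismatches).  Returns the row count."""
    handle.write("gid\tneighbor_gid\tmismatches\n")
    n = 0
    for row in neighborhood_table(index, k_max):
        handle.write(f"{row.gid}\t{row.neighbor_gid}\t{row.mismatches}\n")
        n += 1
    return n
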