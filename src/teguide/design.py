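"""Guide design strategies for transposable elements.

Two strategies are provided:

1. **Single-copy design** — rank every guide occurring inside one TE copy
   by its genome-wide off-target burden, binned by mismatch count
   (0/1/2/3), so the most copy-specific guides come first.

2. **Subfamily combination design** — greedily assemble a combination of
   up to ``combo_size`` guides (default 3) maximizing the combination
   score

   ``SCORE = Coverage − λ1·W1 − λ2·(λ3·W2 + λ4·W3 + λ5·W4 + λ6·W5)``

   where Coverage is the fraction of the subfamily's copies containing at
   least one combination guide site, W1 counts off-target sites inside TE
   copies of *other* subfamilies, and W2..W5 count remaining off-target
   sites in promoter-TSS / exon / intron / intergenic space.  Off-target
   sites are the genomic occurrences of every stored guide within
   ``k_max`` mismatches of a combination member, deduplicated across
   members, excluding sites inside the queried subfamily's own copies.

The greedy procedure seeds with the top ``seed_beam`` guides by
single-guide score, then repeatedly adds the guide with the largest score
increment until the combination is full or no addition helps.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .annotation import (EXON, INTERGENIC, INTRON, PROMOTER,
                         ElementAnnotation, TEAnnotation)
from .index import GuideIndex
from .scoring import ScoreModel

#: W bin index per element class for sites not inside another TE copy.
_ELEMENT_TO_W = {PROMOTER: 2, EXON: 3, INTRON: 4, INTERGENIC: 5}


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the combination search.

    The λ weights mirror the combination-score formula: λ1 penalizes
    off-target sites in other TE copies; λ2 scales the element-class
    penalties λ3 (promoter-TSS), λ4 (exon), λ5 (intron), λ6 (intergenic).
    """

    lambda1: float = 1e-3
    lambda2: float = 1e-4
    lambda3: float = 0.4
    lambda4: float = 0.3
    lambda5: float = 0.4
    lambda6: float = 0.3
    combo_size: int = 3
    seed_beam: int = 10
    k_max: int = 3
    coverage_mismatch: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5", "lambda6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.combo_size < 1:
            raise ValueError("combo_size must be >= 1")
        if not 0 <= self.k_max <= 3:
            raise ValueError("k_max must be in 0..3")
        if not 0 <= self.coverage_mismatch <= self.k_max:
            raise ValueError("coverage_mismatch must be in 0..k_max")


@dataclass(frozen=True)
class OffTargetCounts:
    """Disjoint off-target site counts: W1 = inside other-subfamily TE
    copies, W2..W5 = promoter-TSS / exon / intron / intergenic."""

    w1: int = 0
    w2: int = 0
    w3: int = 0
    w4: int = 0
    w5: int = 0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4, self.w5) < 0:
            raise ValueError("off-target counts must be non-negative")

    @property
    def total(self) -> int:
        return self.w1 + self.w2 + self.w3 + self.w4 + self.w5

    def weighted(self, cfg: DesignConfig) -> float:
        """Total score penalty these counts incur under ``cfg``."""
        return (cfg.lambda1 * self.w1
                + cfg.lambda2 * (cfg.lambda3 * self.w2 + cfg.lambda4 * self.w3
                                 + cfg.lambda5 * self.w4 + cfg.lambda6 * self.w5))

    @classmethod
    def from_bins(cls, bins: Dict[int, int]) -> "OffTargetCounts":
        return cls(*(bins.get(i, 0) for i in range(1, 6)))


def combination_score(coverage: float, counts: OffTargetCounts,
                      cfg: Optional[DesignConfig] = None) -> float:
    """Weighted coverage-minus-off-target score of a guide combination.

    Exact evaluation of ``Coverage − λ1·W1 − λ2·(λ3·W2 + λ4·W3 + λ5·W4 +
    λ6·W5)``; not clamped, so heavily off-targeting combinations may score
    below zero.
    """
    cfg = cfg or DesignConfig()
    return coverage - counts.weighted(cfg)


@dataclass(frozen=True)
class Candidate:
    """Internal summary of one candidate guide for a subfamily query."""

    gid: int
    protospacer: str
    covered: FrozenSet[str]                     # copy_ids hit by this guide
    offsites: Tuple[Tuple[Tuple[str, int, str], int], ...]  # (site key, W bin)
    on_count: int                               # occurrences inside the subfamily


@dataclass
class CombinationResult:
    """An ordered guide combination with its coverage, off-target counts
    and score (reproducible from those via :func:`combination_score`)."""

    gids: List[int]
    protospacers: List[str]
    coverage: float
    covered_copies: FrozenSet[str]
    per_guide_on_target_counts: List[int]
    counts: OffTargetCounts
    score: float

    def to_dict(self) -> dict:
        return {
            "gids": list(self.gids),
            "protospacers": list(self.protospacers),
            "coverage": self.coverage,
            "covered_copies": sorted(self.covered_copies),
            "per_guide_on_target_counts": list(self.per_guide_on_target_counts),
            "W1": self.counts.w1, "W2": self.counts.w2, "W3": self.counts.w3,
            "W4": self.counts.w4, "W5": self.counts.w5,
            "score": self.score,
        }


@dataclass
class SingleCopyGuide:
    """One ranked guide for a single-copy design query."""

    gid: int
    protospacer: str
    site: "object"                # the occurrence inside the queried copy
    gc: float
    mm_counts: Tuple[int, int, int, int]  # other occurrences at 0/1/2/3 mm
    on_target: Optional[float]


# ---------------------------------------------------------------------------
# Candidate extraction against a genome index + annotations
# ---------------------------------------------------------------------------

class SubfamilyDesigner:
    """Caches per-guide neighborhoods and per-site classifications while
    designing against one TE subfamily."""

    def __init__(self, subfamily: str, index: GuideIndex, tes: TEAnnotation,
                 elements: ElementAnnotation, cfg: Optional[DesignConfig] = None):
        self.cfg = cfg or DesignConfig()
        self.subfamily = subfamily
        self.index = index
        self.tes = tes
        self.elements = elements
        copies = tes.copies_of(subfamily)
        if not copies:
            near = difflib.get_close_matches(subfamily, tes.subfamilies, n=3)
            hint = f"; close matches: {', '.join(near)}" if near else ""
            raise ValueError(f"unknown TE subfamily {subfamily!r}{hint}")
        self.copies = copies
        self.copy_ids = {c.copy_id for c in copies}
        self._site_class: Dict[Tuple[str, int, str], Optional[int]] = {}
        self._candidates: Optional[List[Candidate]] = None

    # -- per-site classification ---------------------------------------

    def _classify_occurrence(self, site) -> Optional[int]:
        """W bin (1..5) of an occurrence, or None when the site lies inside
        a queried-subfamily copy (on-target, never counted)."""
        key = site.key()
        if key in self._site_class:
            return self._site_class[key]
        containing = self.tes.containing(site.chrom, site.start, site.end)
        if any(c.subfamily == self.subfamily for c in containing):
            bin_ = None
        elif containing:
            bin_ = 1
        else:
            element = self.elements.classify(site.chrom, site.start, site.end)
            bin_ = _ELEMENT_TO_W[element]
        self._site_class[key] = bin_
        return bin_

    def _covered_by_gid(self, gid: int) -> FrozenSet[str]:
        """Subfamily copies covered by a guide: copies fully containing an
        occurrence of the guide itself or, when coverage_mismatch > 0, of
        any stored neighbor within that many mismatches."""
        rec = self.index.record(gid)
        covered = set()
        if self.cfg.coverage_mismatch == 0:
            neighbor_sites = rec.sites
        else:
            neighbor_sites = []
            for _, ngid, _ in self.index.query(rec.protospacer,
                                               self.cfg.coverage_mismatch):
                neighbor_sites.extend(self.index.record(ngid).sites)
        for site in neighbor_sites:
            for copy in self.tes.containing(site.chrom, site.start, site.end):
                if copy.subfamily == self.subfamily:
                    covered.add(copy.copy_id)
        return frozenset(covered)

    def _offsites_of(self, gid: int) -> Tuple[Tuple[Tuple[str, int, str], int], ...]:
        rec = self.index.record(gid)
        out = {}
        for _, ngid, _ in self.index.query(rec.protospacer, self.cfg.k_max):
            for site in self.index.record(ngid).sites:
                bin_ = self._classify_occurrence(site)
                if bin_ is not None:
                    out[site.key()] = bin_
        return tuple(sorted(out.items()))

    # -- candidates ------------------------------------------------------

    def candidates(self) -> List[Candidate]:
        """All guides with >= 1 occurrence fully contained in a subfamily
        copy, with their coverage sets and classified off-target sites."""
        if self._candidates is not None:
            return self._candidates
        cands = []
        for rec in self.index.records:
            on_count = 0
            for site in rec.sites:
                if any(c.subfamily == self.subfamily for c in
                       self.tes.containing(site.chrom, site.start, site.end)):
                    on_count += 1
            if on_count == 0:
                continue
            cands.append(Candidate(rec.gid, rec.protospacer,
                                   self._covered_by_gid(rec.gid),
                                   self._offsites_of(rec.gid), on_count))
        self._candidates = cands
        return cands

    def coverage_of(self, gids: Iterable[int]) -> Tuple[float, FrozenSet[str]]:
        covered: set = set()
        for gid in gids:
            covered |= self._covered_by_gid(gid)
        return len(covered) / len(self.copies), frozenset(covered)

    def counts_of(self, gids: Iterable[int]) -> OffTargetCounts:
        union: Dict[Tuple[str, int, str], int] = {}
        for gid in gids:
            union.update(self._offsites_of(gid))
        bins: Dict[int, int] = {}
        for bin_ in union.values():
            bins[bin_] = bins.get(bin_, 0) + 1
        return OffTargetCounts.from_bins(bins)


def subfamily_coverage(gids: Iterable[int], subfamily: str, index: GuideIndex,
                       tes: TEAnnotation,
                       cfg: Optional[DesignConfig] = None
                       ) -> Tuple[float, FrozenSet[str]]:
    """Fraction (and set) of a subfamily's copies covered by a guide set.
    A copy is covered iff at least one guide has an occurrence — within
    ``coverage_mismatch`` mismatches, default exact — fully contained in it."""
    designer = SubfamilyDesigner(subfamily, index, tes,
                                 ElementAnnotation(), cfg)
    return designer.coverage_of(gids)


def offtarget_counts(gids: Iterable[int], subfamily: str, index: GuideIndex,
                     tes: TEAnnotation, elements: ElementAnnotation,
                     cfg: Optional[DesignConfig] = None) -> OffTargetCounts:
    """Deduplicated W1..W5 off-target site counts of a guide set against a
    subfamily (see module docstring for the binning rule)."""
    designer = SubfamilyDesigner(subfamily, index, tes, elements, cfg)
    return designer.counts_of(gids)


# ---------------------------------------------------------------------------
# Greedy combination search
# ---------------------------------------------------------------------------

def _merge_state(cov: FrozenSet[str], offs: Dict, cand: Candidate
                 ) -> Tuple[FrozenSet[str], Dict]:
    ncov = cov | cand.covered
    noffs = dict(offs)
    noffs.update(cand.offsites)
    return ncov, noffs


def _counts_from(offs: Dict) -> OffTargetCounts:
    bins: Dict[int, int] = {}
    for b in offs.values():
        bins[b] = bins.get(b, 0) + 1
    return OffTargetCounts.from_bins(bins)


def greedy_select(candidates: Sequence[Candidate], n_total_copies: int,
                  cfg: Optional[DesignConfig] = None) -> List[Tuple[List[Candidate], float]]:
    """Core greedy procedure over precomputed candidates.

    Ranks candidates by single-guide score (ties: higher coverage, lower
    weighted off-target penalty, lexicographically smallest protospacer),
    expands each of the top ``seed_beam`` seeds by repeatedly adding the
    guide with the largest strictly positive score increment, and returns
    the (combination, final score) list sorted by final score descending.
    """
    cfg = cfg or DesignConfig()
    if not candidates:
        return []

    def single_key(c: Candidate):
        counts = _counts_from(dict(c.offsites))
        s = combination_score(len(c.covered) / n_total_copies, counts, cfg)
        return (-s, -len(c.covered), counts.weighted(cfg), c.protospacer)

    seeds = sorted(candidates, key=single_key)[:cfg.seed_beam]
    results: List[Tuple[List[Candidate], float]] = []
    for seed_rank, seed in enumerate(seeds):
        chosen = [seed]
        cov: FrozenSet[str] = seed.covered
        offs: Dict = dict(seed.offsites)
        cur = combination_score(len(cov) / n_total_copies, _counts_from(offs), cfg)
        while len(chosen) < cfg.combo_size:
            chosen_gids = {c.gid for c in chosen}
            best = None
            for cand in candidates:
                if cand.gid in chosen_gids:
                    continue
                ncov, noffs = _merge_state(cov, offs, cand)
                ncounts = _counts_from(noffs)
                s = combination_score(len(ncov) / n_total_copies, ncounts, cfg)
                key = (-s, -len(ncov), ncounts.weighted(cfg), cand.protospacer)
                if best is None or key < best[0]:
                    best = (key, cand, s, ncov, noffs)
            if best is None or best[2] - cur <= 0:
                break
            _, cand, cur, cov, offs = best
            chosen.append(cand)
        results.append((seed_rank, chosen, cur))
    # equal final scores resolve in favour of the better-ranked seed, so
    # the top result is the top seed's documented trace
    results.sort(key=lambda r: (-r[2], r[0]))
    return [(chosen, score) for _, chosen, score in results]


def greedy_combination(subfamily: str, index: GuideIndex, tes: TEAnnotation,
                       elements: ElementAnnotation,
                       cfg: Optional[DesignConfig] = None
                       ) -> List[CombinationResult]:
    """Greedy combination search for a TE subfamily.

    Returns one :class:`CombinationResult` per expanded seed (best first);
    an empty list when the subfamily contains no candidate guide.
    """
    cfg = cfg or DesignConfig()
    designer = SubfamilyDesigner(subfamily, index, tes, elements, cfg)
    candidates = designer.candidates()
    raw = greedy_select(candidates, len(designer.copies), cfg)
    results = []
    for chosen, score in raw:
        covered: FrozenSet[str] = frozenset().union(*(c.covered for c in chosen))
        offs: Dict = {}
        for c in chosen:
            offs.update(c.offsites)
        counts = _counts_from(offs)
        results.append(CombinationResult(
            gids=[c.gid for c in chosen],
            protospacers=[c.protospacer for c in chosen],
            coverage=len(covered) / len(designer.copies),
            covered_copies=covered,
            per_guide_on_target_counts=[c.on_count for c in chosen],
            counts=counts,
            score=score,
        ))
    return results


# ---------------------------------------------------------------------------
# Single-copy design
# ---------------------------------------------------------------------------

def single_copy_design(copy_id: str, index: GuideIndex, tes: TEAnnotation,
                       cfg: Optional[DesignConfig] = None,
                       score_model: Optional[ScoreModel] = None
                       ) -> List[SingleCopyGuide]:
    """Rank guides inside one TE copy by genome-wide off-target burden.

    For every guide with an occurrence fully contained in the copy, other
    genomic occurrences of its mismatch neighborhood are binned by
    distance (0..k_max mismatches; occurrences inside the queried copy
    excluded).  Guides are ranked ascending by (mm0, mm1, mm2, mm3), then
    descending on-target score (missing scores last), then protospacer.
    """
    cfg = cfg or DesignConfig()
    copy = tes.by_id.get(copy_id)
    if copy is None:
        near = difflib.get_close_matches(copy_id, list(tes.by_id), n=3)
        hint = f"; close matches: {', '.join(near)}" if near else ""
        raise ValueError(f"unknown TE copy id {copy_id!r}{hint}")
    rows: List[SingleCopyGuide] = []
    for rec in index.records:
        inside = [s for s in rec.sites
                  if copy.contains(s.chrom, s.start, s.end)]
        if not inside:
            continue
        bins = [0, 0, 0, 0]
        for _, ngid, mm in index.query(rec.protospacer, cfg.k_max):
            for site in index.record(ngid).sites:
                if copy.contains(site.chrom, site.start, site.end):
                    continue
                bins[mm] += 1
        on_target = None
        if score_model is not None:
            on_target = score_model.score(inside[0].context30())
        rows.append(SingleCopyGuide(rec.gid, rec.protospacer, inside[0],
                                    rec.gc, tuple(bins), on_target))
    rows.sort(key=lambda r: (r.mm_counts,
                             r.on_target is None,
                             -(r.on_target or 0.0),
                             r.protospacer))
    return rows
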