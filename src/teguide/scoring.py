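"""Pluggable on-target activity and off-target specificity scoring.

On-target activity is a linear feature model over a 30-nt context
(4 nt upstream + 20-nt protospacer + 3-nt PAM + 3 nt downstream): the
score is ``link(intercept + sum of matched position/pattern weights)``
clamped to [0, 1].  Off-target specificity aggregates per-off-target
penalty factors, each the product of position-wise mismatch factors over
the 20-nt protospacer, into ``100 / (1 + sum of penalties)`` — 100 for a
genome-unique guide, strictly decreasing as off-targets accumulate.

Both the weight table and the mismatch-penalty table are plain TSV files
so published tables (position-specific activity models, CFD-style
mismatch factors) can be dropped in.  The bundled defaults under
``teguide/data`` are synthetic tables of the package's own design — see
their headers — chosen for qualitative realism (PAM-proximal mismatches
disrupt binding most), not transcriptions of any published model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Dict, Iterable, List, Optional, Tuple

from .scan import PROTOSPACER_LEN

LINKS = ("identity-clamped", "logistic")


def _parse_header(line: str) -> Dict[str, str]:
    if not line.startswith("#"):
        raise ValueError("score table must start with a '# key=value ...' header")
    out = {}
    for token in line.lstrip("#").split():
        key, _, value = token.partition("=")
        out[key] = value
    return out


@dataclass
class ScoreModel:
    """Linear position/pattern activity model over a fixed-length context.

    ``weights`` maps (1-based context position, nucleotide or dinucleotide
    pattern) to an additive weight.  The model is fully determined by its
    table; identical inputs give bit-identical scores.
    """

    name: str = "uniform"
    context_length: int = 30
    link: str = "identity-clamped"
    intercept: float = 0.0
    weights: Dict[Tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; expected one of {LINKS}")

    def score(self, context: str) -> Optional[float]:
        """Score a context; None when the context is missing or contains
        ambiguity codes (recorded as absent, never fabricated)."""
        if context is None:
            return None
        context = context.upper()
        if len(context) != self.context_length:
            raise ValueError(
                f"context must be {self.context_length} nt, got {len(context)}")
        if any(ch not in "ACGT" for ch in context):
            return None
        raw = self.intercept
        for (pos, pattern), w in self.weights.items():
            if context[pos - 1:pos - 1 + len(pattern)] == pattern:
                raw += w
        if self.link == "logistic":
            raw = 1.0 / (1.0 + math.exp(-raw))
        return min(1.0, max(0.0, raw))

    @classmethod
    def from_tsv(cls, handle: IO[str]) -> "ScoreModel":
        header = _parse_header(handle.readline())
        model = cls(name=header.get("name", "unnamed"),
                    context_length=int(header.get("context_length", 30)),
                    link=header.get("link", "identity-clamped"),
                    intercept=float(header.get("intercept", 0.0)))
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            pos, pattern, weight = line.split("\t")
            model.weights[(int(pos), pattern)] = float(weight)
        return model

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write(f"# name={self.name} context_length={self.context_length} "
                     f"link={self.link} intercept={self.intercept}\n")
        handle.write("position\tpattern\tweight\n")
        for (pos, pattern), w in sorted(self.weights.items()):
            handle.write(f"{pos}\t{pattern}\t{w}\n")


@dataclass
class MismatchPenaltyTable:
    """Per-position mismatch penalty factors in [0, 1].

    ``factors`` maps (protospacer position 1..20, reference nt, off-target
    nt) to the relative activity retained at an off-target carrying that
    single mismatch; a matching position always contributes factor 1.
    """

    name: str = "unnamed"
    factors: Dict[Tuple[int, str, str], float] = field(default_factory=dict)

    def factor(self, position: int, ref: str, obs: str) -> float:
        if ref == obs:
            return 1.0
        try:
            f = self.factors[(position, ref, obs)]
        except KeyError:
            raise ValueError(
                f"penalty table {self.name!r} has no factor for "
                f"position {position} {ref}->{obs}") from None
        return f

    @classmethod
    def from_tsv(cls, handle: IO[str]) -> "MismatchPenaltyTable":
        header = _parse_header(handle.readline())
        table = cls(name=header.get("name", "unnamed"))
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            pos, ref, obs, factor = line.split("\t")
            value = float(factor)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"penalty factor out of [0,1]: {line!r}")
            table.factors[(int(pos), ref, obs)] = value
        return table

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write(f"# name={self.name}\n")
        handle.write("position\tref\tobs\tfactor\n")
        for (pos, ref, obs), f in sorted(self.factors.items()):
            handle.write(f"{pos}\t{ref}\t{obs}\t{f}\n")


def site_penalty(table: MismatchPenaltyTable, guide: str, offtarget: str) -> float:
    """Product of per-position mismatch factors between a guide and one
    off-target protospacer; 1.0 for identical sequences."""
    if len(guide) != PROTOSPACER_LEN or len(offtarget) != PROTOSPACER_LEN:
        raise ValueError("guide and off-target must both be 20 nt")
    penalty = 1.0
    for i, (ref, obs) in enumerate(zip(guide.upper(), offtarget.upper()), start=1):
        if ref != obs:
            penalty *= table.factor(i, ref, obs)
    return penalty


def specificity_score(offtarget_penalties: Iterable[float]) -> float:
    """Aggregate off-target penalties into a [0, 100] specificity score:
    ``100 / (1 + sum of penalties)``.  100 with no off-targets; strictly
    decreasing in every penalty."""
    return 100.0 / (1.0 + sum(offtarget_penalties))


def guide_specificity(index, gid: int, table: MismatchPenaltyTable,
                      k_max: int = 3) -> float:
    """Specificity of a stored guide against its whole mismatch
    neighborhood; every occurrence of every neighbor (distance >= 1)
    contributes one penalty term."""
    rec = index.record(gid)
    penalties: List[float] = []
    for nproto, ngid, mm in index.query(rec.protospacer, k_max):
        if ngid == gid:
            continue
        p = site_penalty(table, rec.protospacer, nproto)
        penalties.extend([p] * len(index.record(ngid).sites))
    return specificity_score(penalties)


def _open_data(filename: str):
    return resources.files("teguide.data").joinpath(filename).open("r")


def default_on_target_model() -> ScoreModel:
    """Bundled synthetic default activity model (see data file header)."""
    with _open_data("on_target_default.synthetic.tsv") as fh:
        return ScoreModel.from_tsv(fh)


def default_mismatch_penalties() -> MismatchPenaltyTable:
    """Bundled synthetic default mismatch-penalty table: factors decline
    linearly from PAM-distal to PAM-proximal positions, uniformly over
    nucleotide identities."""
    with _open_data("mismatch_penalty_default.synthetic.tsv") as fh:
        return MismatchPenaltyTable.from_tsv(fh)
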