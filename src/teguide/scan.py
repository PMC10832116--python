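"""Genome-wide enumeration of SpCas9 target sites.

A target site is a 23-bp genomic window consisting of a 20-nt protospacer
followed by a 3-nt PAM (5'-NGG-3' for SpCas9; any 3-symbol IUPAC pattern
may be supplied).  Both strands are scanned; a site is reported in spacer
orientation, i.e. the protospacer reads 5'->3' as the sgRNA spacer would
base-pair with the target.  Six bases of flanking context on either side
are captured for downstream activity scoring, padded with ``N`` where a
site lies within 6 bp of a contig edge.

Coordinates are 0-based half-open over the 23-bp protospacer+PAM interval
on the forward reference strand, regardless of the site's strand.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Tuple, Union

from Bio import SeqIO

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN
FLANK_LEN = 6

#: IUPAC nucleotide codes -> the set of unambiguous bases they match.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(protospacer: str) -> float:
    """GC fraction of a 20-nt protospacer.

    Raises
    ------
    ValueError
        If the sequence is not exactly 20 unambiguous bases.
    """
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(
            f"protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}"
        )
    seq = protospacer.upper()
    if any(ch not in "ACGT" for ch in seq):
        raise ValueError(f"invalid protospacer sequence: {protospacer!r}")
    return (seq.count("G") + seq.count("C")) / PROTOSPACER_LEN


@dataclass(frozen=True, slots=True)
class GuideSite:
    """One genomic occurrence of a protospacer+PAM site.

    ``genome[start:end]`` equals ``protospacer + pam`` on the ``+`` strand
    and its reverse complement on the ``-`` strand.  ``upstream6`` /
    ``downstream6`` are the 6 bases 5' of the protospacer and 3' of the
    PAM respectively, in spacer orientation.
    """

    chrom: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    upstream6: str
    downstream6: str

    def context30(self) -> str | None:
        """4-nt upstream + protospacer + PAM + 3-nt downstream context.

        Returns None when the context runs off a contig edge (contains N);
        callers record the on-target score as missing in that case.
        """
        ctx = self.upstream6[-4:] + self.protospacer + self.pam + self.downstream6[:3]
        return None if "N" in ctx else ctx

    def key(self) -> Tuple[str, int, str]:
        """Identity of a genomic occurrence: (chrom, start, strand)."""
        return (self.chrom, self.start, self.strand)


def _pam_char_class(symbol: str) -> str:
    bases = IUPAC_CODES[symbol]
    return bases if len(bases) == 1 else f"[{bases}]"


def _compile_pam(pam_rule: str) -> tuple[re.Pattern, re.Pattern]:
    pam_rule = pam_rule.upper()
    if len(pam_rule) != PAM_LEN or any(s not in IUPAC_CODES for s in pam_rule):
        raise ValueError(f"PAM rule must be a 3-symbol IUPAC pattern, got {pam_rule!r}")
    fwd = "".join(_pam_char_class(s) for s in pam_rule)
    rev = "".join(_pam_char_class(s) for s in revcomp(pam_rule))
    # Look-ahead groups so overlapping sites are all found.
    plus = re.compile(rf"(?=([ACGT]{{{PROTOSPACER_LEN}}}{fwd}))")
    minus = re.compile(rf"(?=({rev}[ACGT]{{{PROTOSPACER_LEN}}}))")
    return plus, minus


FastaInput = Union[str, Path, IO[str], Mapping[str, str]]


def _iter_sequences(fasta: FastaInput) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs in input order from a FASTA path,
    open handle, or an in-memory mapping."""
    if isinstance(fasta, Mapping):
        for name, seq in fasta.items():
            yield name, str(seq)
        return
    if isinstance(fasta, (str, Path)):
        path = Path(fasta)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from _iter_fasta_handle(fh, str(path))
    else:
        yield from _iter_fasta_handle(fasta, getattr(fasta, "name", "<stream>"))


def _iter_fasta_handle(fh: IO[str], label: str) -> Iterator[tuple[str, str]]:
    saw_record = False
    for rec in SeqIO.parse(fh, "fasta"):
        if not rec.id:
            raise ValueError(f"malformed FASTA record without a name in {label}")
        saw_record = True
        yield rec.id, str(rec.seq)
    if not saw_record:
        # SeqIO silently yields nothing for non-FASTA text; distinguish an
        # empty file (valid: empty genome) from garbage input.
        try:
            fh.seek(0)
            head = fh.read(1024).lstrip()
        except (OSError, ValueError):
            head = ""
        if head and not head.startswith(">"):
            raise ValueError(f"malformed FASTA: {label} does not start with '>'")


def scan_genome(fasta: FastaInput, pam_rule: str = "NGG") -> Iterator[GuideSite]:
    """Enumerate every candidate target site on both strands of a genome.

    Emits every 23-bp window whose last 3 bases match ``pam_rule`` on the
    forward strand, and every window whose reverse complement does, in
    deterministic order: contigs in input order, then start ascending,
    then ``+`` before ``-``.  Windows containing ambiguity codes are never
    emitted; soft-masked (lower-case) sequence is upper-cased first.
    """
    plus_re, minus_re = _compile_pam(pam_rule)
    for chrom, raw in _iter_sequences(fasta):
        seq = raw.upper()
        events: list[tuple[int, int]] = []
        events.extend((m.start(), 0) for m in plus_re.finditer(seq))
        events.extend((m.start(), 1) for m in minus_re.finditer(seq))
        events.sort()
        for start, is_minus in events:
            end = start + SITE_LEN
            window = seq[start:end]
            if is_minus:
                proto = revcomp(window[PAM_LEN:])
                pam = revcomp(window[:PAM_LEN])
                up = revcomp(seq[end:end + FLANK_LEN]).rjust(FLANK_LEN, "N")
                down = revcomp(seq[max(0, start - FLANK_LEN):start]).ljust(FLANK_LEN, "N")
                strand = "-"
            else:
                proto = window[:PROTOSPACER_LEN]
                pam = window[PROTOSPACER_LEN:]
                up = seq[max(0, start - FLANK_LEN):start].rjust(FLANK_LEN, "N")
                down = seq[end:end + FLANK_LEN].ljust(FLANK_LEN, "N")
                strand = "+"
            yield GuideSite(chrom, start, end, strand, proto, pam, up, down)


def sites_to_bed(sites: Iterable[GuideSite], handle: IO[str]) -> int:
    """Write sites as BED6+ (chrom, start, end, protospacer, '.', strand,
    pam, upstream6, downstream6).  Returns the number of rows written."""
    n = 0
    for s in sites:
        handle.write(
            f"{s.chrom}\t{s.start}\t{s.end}\t{s.protospacer}\t.\t{s.strand}"
            f"\t{s.pam}\t{s.upstream6}\t{s.downstream6}\n"
        )
        n += 1
    return n
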