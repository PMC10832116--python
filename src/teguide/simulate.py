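"""Synthetic genomes with planted TE subfamilies and a toy gene model.

The simulator emulates the one property of real TE landscapes that drives
guide design difficulty: per-copy sequence divergence from a subfamily
consensus, which grows with the subfamily's evolutionary age.  Each
subfamily draws a random consensus once; every copy is the consensus with
i.i.d. substitutions at rate ``divergence`` and, optionally, a 5'
truncation.  Decoy subfamilies (a mutated clone of a focal consensus
under another name) exercise cross-subfamily off-target counting.  A toy
gene model (uniform exon/intron ladders) provides promoter/exon/intron
annotation.  Copies and genes are placed without overlap on i.i.d.
background sequence.

Outputs are standard formats — FASTA, RepeatMasker ``.out``, GTF — plus a
JSON manifest recording every planted interval with its realized
divergence, which downstream tests use as exact ground truth.  Identical
seed and parameters give byte-identical outputs; each subfamily, the
background, the gene model and the placement each consume an independent
spawned RNG stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import ElementAnnotation, TEAnnotation, assign_copy_ids
from .scan import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SubfamilySpec:
    """One planted TE subfamily.

    ``divergence`` is the per-base substitution probability applied
    independently to every copy (0 = identical copies, the signature of a
    young subfamily).  A decoy subfamily copies another subfamily's
    consensus mutated at ``decoy_divergence`` before planting its own
    copies, emulating related subfamilies that attract cross-subfamily
    off-targets.
    """

    name: str
    consensus_length: int = 300
    n_copies: int = 50
    divergence: float = 0.05
    truncation_prob: float = 0.0
    truncation_max_frac: float = 0.5
    te_class: str = "LTR"
    family: str = "ERVK"
    decoy_of: Optional[str] = None
    decoy_divergence: float = 0.15


@dataclass
class GeneModelSpec:
    """Uniform toy gene model: each gene is one transcript of
    ``exons_per_gene`` exons separated by introns."""

    n_genes: int = 4
    exons_per_gene: int = 3
    exon_length: int = 150
    intron_length: int = 400
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    @property
    def transcript_length(self) -> int:
        return (self.exons_per_gene * self.exon_length
                + (self.exons_per_gene - 1) * self.intron_length)


@dataclass
class SimulationParams:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 25000
    background_gc: float = 0.41
    subfamilies: List[SubfamilySpec] = field(
        default_factory=lambda: [SubfamilySpec("TEsim1")])
    genes: GeneModelSpec = field(default_factory=GeneModelSpec)
    min_gap: int = 30

    def validate(self) -> None:
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0,1]")
        names = set()
        for sf in self.subfamilies:
            if not 0.0 <= sf.divergence <= 1.0:
                raise ValueError(f"{sf.name}: divergence must be in [0,1]")
            if not 0.0 <= sf.truncation_prob <= 1.0:
                raise ValueError(f"{sf.name}: truncation_prob must be in [0,1]")
            if sf.name in names:
                raise ValueError(f"duplicate subfamily name {sf.name}")
            names.add(sf.name)
            if sf.decoy_of is not None and sf.decoy_of not in names:
                raise ValueError(
                    f"{sf.name}: decoy_of {sf.decoy_of!r} must be declared earlier")

    # -- JSON round trip for CLI / manifests -----------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        d["subfamilies"] = [SubfamilySpec(**s) for s in d.get("subfamilies", [])]
        if "genes" in d:
            d["genes"] = GeneModelSpec(**d["genes"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedCopy:
    """Ground truth for one planted TE copy."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    te_class: str
    copy_id: str
    n_substitutions: int
    divergence: float
    truncated_by: int
    sequence: str  # consensus-oriented (5'->3' of the element)


@dataclass(frozen=True)
class PlantedGene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]


@dataclass
class SimulatedGenome:
    params: SimulationParams
    sequences: Dict[str, str]
    te_copies: List[PlantedCopy]
    genes: List[PlantedGene]
    consensus: Dict[str, str]

    def to_te_annotation(self) -> TEAnnotation:
        copies = assign_copy_ids(
            [(c.chrom, c.start, c.end, c.strand, c.subfamily, c.family,
              c.te_class) for c in self.te_copies],
            chrom_order=list(self.sequences))
        return TEAnnotation(copies)

    def to_element_annotation(self) -> ElementAnnotation:
        gm = self.params.genes
        return ElementAnnotation.from_transcripts(
            [(g.chrom, g.strand, list(g.exons)) for g in self.genes],
            promoter_window=(gm.promoter_upstream, gm.promoter_downstream))

    def manifest(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "chromosomes": {name: len(seq) for name, seq in self.sequences.items()},
            "consensus": dict(self.consensus),
            "te_copies": [dataclasses.asdict(c) for c in self.te_copies],
            "genes": [dataclasses.asdict(g) for g in self.genes],
        }

    def write(self, out_dir: str | Path) -> Dict[str, Path]:
        """Write FASTA, RepeatMasker .out, GTF and the JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": out / "genome.fa", "te_out": out / "repeats.out",
                 "gtf": out / "genes.gtf", "manifest": out / "manifest.json"}
        with open(paths["fasta"], "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(paths["te_out"], "w") as fh:
            fh.write("   SW   perc perc perc  query     position in query"
                     "            matching  repeat\n"
                     "score   div. del. ins.  sequence  begin  end   (left)"
                     "    repeat    class/family\n\n")
            for i, c in enumerate(self.te_copies, start=1):
                left = len(self.sequences[c.chrom]) - c.end
                strand = "+" if c.strand == "+" else "C"
                fh.write(f"{1000:5d} {c.divergence * 100:5.1f}  0.0  0.0  "
                         f"{c.chrom} {c.start + 1} {c.end} ({left}) {strand} "
                         f"{c.subfamily} {c.te_class}/{c.family} "
                         f"1 {len(c.sequence)} (0) {i}\n")
        with open(paths["gtf"], "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.name}"; transcript_id "{g.name}.t1";'
                fh.write(f"{g.chrom}\tteguide_sim\tgene\t{g.start + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t.\t{attrs}\n")
                fh.write(f"{g.chrom}\tteguide_sim\ttranscript\t{g.start + 1}"
                         f"\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
                for es, ee in g.exons:
                    fh.write(f"{g.chrom}\tteguide_sim\texon\t{es + 1}\t{ee}"
                             f"\t.\t{g.strand}\t.\t{attrs}\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at, gccomp = (1.0 - gc) / 2.0, gc / 2.0
    probs = [at, gccomp, gccomp, at]  # A C G T
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, int]:
    """Apply i.i.d. substitutions at the given per-base rate; each hit base
    is replaced by one of the three alternatives uniformly."""
    if rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alternatives = _BASES[_BASES != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return arr.tobytes().decode(), len(hits)


def simulate_genome(params: SimulationParams,
                    out_dir: Optional[str | Path] = None) -> SimulatedGenome:
    """Generate a synthetic genome with planted TE copies and genes.

    Raises a sizing error naming the shortfall when the requested features
    do not fit on the requested chromosomes.
    """
    params.validate()
    root = np.random.default_rng(params.seed)
    n_sub = len(params.subfamilies)
    streams = root.spawn(3 + n_sub)
    bg_rng, place_rng, gene_rng = streams[0], streams[1], streams[2]
    sub_rngs = streams[3:]

    # consensus sequences (decoys derive from their focal consensus)
    consensus: Dict[str, str] = {}
    for sf, rng in zip(params.subfamilies, sub_rngs):
        if sf.decoy_of is not None:
            base = consensus[sf.decoy_of]
            consensus[sf.name], _ = _mutate(rng, base, sf.decoy_divergence)
        else:
            consensus[sf.name] = _random_dna(rng, sf.consensus_length, 0.5)

    # features to place: (kind, payload, length)
    features: List[tuple] = []
    for sf, rng in zip(params.subfamilies, sub_rngs):
        cons = consensus[sf.name]
        for _ in range(sf.n_copies):
            seq, _ = _mutate(rng, cons, sf.divergence)
            truncated_by = 0
            if sf.truncation_prob > 0 and rng.random() < sf.truncation_prob:
                max_cut = max(1, int(sf.truncation_max_frac * len(seq)))
                truncated_by = int(rng.integers(1, max_cut + 1))
                seq = seq[truncated_by:]
            strand = "+" if rng.random() < 0.5 else "-"
            nsub = sum(a != b for a, b in zip(seq, cons[truncated_by:]))
            features.append(("te", (sf, seq, strand, nsub, truncated_by), len(seq)))
    gm = params.genes
    for gi in range(gm.n_genes):
        strand = "+" if gene_rng.random() < 0.5 else "-"
        features.append(("gene", (f"gene{gi + 1}", strand), gm.transcript_length))

    # deterministic placement: permute, balance across chromosomes by
    # load, then left-to-right with random gaps filling the slack
    order = place_rng.permutation(len(features))
    features = [features[i] for i in order]
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms)]
    per_chrom: Dict[str, List[tuple]] = {c: [] for c in chrom_names}
    loads = {c: 0 for c in chrom_names}
    for feat in features:
        target = min(chrom_names, key=lambda c: (loads[c], c))
        needed = loads[target] + feat[2] + params.min_gap * (len(per_chrom[target]) + 2)
        if needed > params.chrom_length:
            total = sum(f[2] for f in features)
            raise ValueError(
                f"genome too small: {total} bp of features (+gaps) exceed "
                f"{params.n_chroms} x {params.chrom_length} bp; "
                f"chromosome {target} overflows by {needed - params.chrom_length} bp")
        per_chrom[target].append(feat)
        loads[target] += feat[2] + params.min_gap

    sequences: Dict[str, str] = {}
    te_rows: List[tuple] = []
    genes: List[PlantedGene] = []
    for chrom in chrom_names:
        feats = per_chrom[chrom]
        background = np.frombuffer(
            _random_dna(bg_rng, params.chrom_length, params.background_gc
                        ).encode(), dtype="S1").copy()
        slack = params.chrom_length - sum(f[2] for f in feats) \
            - params.min_gap * (len(feats) + 1)
        weights = place_rng.random(len(feats) + 1)
        gaps = np.floor(weights / weights.sum() * max(slack, 0)).astype(int)
        cursor = 0
        for i, (kind, payload, length) in enumerate(feats):
            cursor += params.min_gap + int(gaps[i])
            start, end = cursor, cursor + length
            if kind == "te":
                sf, seq, strand, nsub, truncated_by = payload
                genomic = seq if strand == "+" else revcomp(seq)
                background[start:end] = np.frombuffer(genomic.encode(), dtype="S1")
                te_rows.append((chrom, start, end, strand, sf, seq, nsub,
                                truncated_by))
            else:
                name, strand = payload
                exons = tuple(
                    (start + k * (gm.exon_length + gm.intron_length),
                     start + k * (gm.exon_length + gm.intron_length) + gm.exon_length)
                    for k in range(gm.exons_per_gene))
                genes.append(PlantedGene(name, chrom, start, end, strand, exons))
            cursor = end
        sequences[chrom] = background.tobytes().decode()

    # copy ids: same rule the RepeatMasker parser uses
    te_rows.sort(key=lambda r: (chrom_names.index(r[0]), r[1]))
    counters: Dict[str, int] = {}
    copies: List[PlantedCopy] = []
    for chrom, start, end, strand, sf, seq, nsub, truncated_by in te_rows:
        counters[sf.name] = counters.get(sf.name, 0) + 1
        copies.append(PlantedCopy(
            chrom, start, end, strand, sf.name, sf.family, sf.te_class,
            f"{sf.name}_dup{counters[sf.name]}", nsub,
            nsub / len(seq) if seq else 0.0, truncated_by, seq))

    sim = SimulatedGenome(params, sequences, copies, genes, consensus)
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def default_params(seed: int = 0, divergence: float = 0.05) -> SimulationParams:
    """Study conditions used throughout the package's own experiments:
    a focal 300-bp, 50-copy subfamily at the given divergence, a 10-copy
    decoy at 15% divergence from the focal consensus, and a 4-gene toy
    gene model on 2 x 25-kb chromosomes."""
    return SimulationParams(
        seed=seed,
        n_chroms=2,
        chrom_length=25000,
        subfamilies=[
            SubfamilySpec("ERVsim", consensus_length=300, n_copies=50,
                          divergence=divergence),
            SubfamilySpec("ERVdecoy", consensus_length=300, n_copies=10,
                          divergence=0.05, decoy_of="ERVsim",
                          decoy_divergence=0.15, family="ERVK-decoy"),
        ],
        genes=GeneModelSpec(n_genes=4),
    )


def age_coverage_experiment(base_params: SimulationParams,
                            divergence_grid: Sequence[float] = (0.0, 0.05, 0.15, 0.25),
                            focal: Optional[str] = None,
                            cfg=None,
                            plot_path: Optional[str | Path] = None):
    """Best-combination coverage of the focal subfamily across a grid of
    per-copy divergences (a proxy for subfamily age).

    Runs the full pipeline — simulate, scan, index, annotate, greedy
    combination search — once per grid point with the same seed, copy
    number and consensus length, and returns a DataFrame with columns
    (divergence, coverage, score, w1..w5).
    """
    import pandas as pd

    from .design import greedy_combination
    from .index import build_index
    from .scan import scan_genome

    if sorted(divergence_grid) != list(divergence_grid):
        raise ValueError("divergence_grid must be sorted ascending")
    if focal is None:
        focal = next(sf.name for sf in base_params.subfamilies
                     if sf.decoy_of is None)
    rows = []
    for d in divergence_grid:
        params = SimulationParams.from_dict(base_params.to_dict())
        for sf in params.subfamilies:
            if sf.name == focal:
                sf.divergence = d
        sim = simulate_genome(params)
        index = build_index(scan_genome(sim.sequences))
        combos = greedy_combination(focal, index, sim.to_te_annotation(),
                                    sim.to_element_annotation(), cfg)
        best = combos[0] if combos else None
        rows.append({
            "divergence": d,
            "coverage": best.coverage if best else 0.0,
            "score": best.score if best else 0.0,
            "w1": best.counts.w1 if best else 0,
            "w2": best.counts.w2 if best else 0,
            "w3": best.counts.w3 if best else 0,
            "w4": best.counts.w4 if best else 0,
            "w5": best.counts.w5 if best else 0,
        })
    table = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(table["divergence"], table["coverage"], marker="o")
        ax.set_xlabel("per-copy divergence from consensus")
        ax.set_ylabel("best combination coverage")
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table
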