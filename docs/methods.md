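# Methods

## The design problem

A TE subfamily is a set of genomic copies descended from one consensus
sequence. Young subfamilies have near-identical copies, so a single
20-nt protospacer can occur in most of them; old subfamilies have
diverged, and no small guide set reaches every copy. Conversely, the
same interspersed homology creates dense near-match off-target space in
related subfamilies and in genes. `teguide` treats guide design for TEs
as a coverage-versus-off-target trade-off over an exhaustive, exact site
inventory.

## Site inventory and mismatch index

Every 23-bp window on either strand whose final 3 bases match the PAM
pattern (default NGG, any 3-symbol IUPAC pattern accepted) and whose
23-mer is free of ambiguity codes is a site. Soft-masking is ignored
(TEs are routinely soft-masked; excluding them would remove the
targets). Windows containing N are never emitted; only the 6-bp flank
context may be N-padded at contig edges, and a site whose 30-nt scoring
context is incomplete carries an *absent* on-target score rather than a
fabricated one. Coordinates are 0-based half-open internally over the
full 23-bp protospacer+PAM interval; all user-facing tables print
1-based inclusive coordinates.

Unique protospacers are stored in a 4-ary trie; ids (gids) are assigned
in lexicographic sequence order so rebuilds are reproducible. A
neighborhood query walks the trie depth-first with a running mismatch
budget, pruning when the accumulated Hamming distance exceeds k; this is
exact (tests compare against exhaustive enumeration). The model is
substitution-only — no bulges — and an off-target must itself be a
stored site, i.e. it carries its own PAM; PAM-less near-matches are
invisible by construction. The neighborhood radius is configurable with
default k_max = 3 (reported off-target bins are 0/1/2/3 mismatches).

## Annotation

TE copies come from RepeatMasker `.out` (1-based inclusive coordinates
converted on parse; strand `C` → `-`). Copy ids are
`<subfamily>_dup<i>` with `i` the 1-based rank among the subfamily's
copies ordered by (chromosome order, start); this convention is the
package's own. A site *targets* a copy only when its whole 23-bp
interval is contained in the copy — containment makes "this guide cuts
this copy" unambiguous — and nested copies resolve to the smallest
container. Genetic-element classes use any-overlap with precedence
promoter-TSS > exon > intron > intergenic; the promoter window is
(−1000, +100) around the strand-aware TSS, a common default, and is
configurable. Classification is total: every position gets exactly one
class.

## Scoring

On-target activity is a pluggable linear model over a 30-nt context
(4 nt upstream + protospacer + PAM + 3 nt downstream):
`link(intercept + Σ matched position/pattern weights)` clamped to
[0, 1]. Off-target penalties are products of per-position mismatch
factors over the protospacer, aggregated per guide into a specificity
score `100 / (1 + Σ penalties)` — 100 for a genome-unique guide,
strictly decreasing as off-targets accumulate (every genomic occurrence
of every neighbor contributes one term). The aggregation form is the
package's own choice: it is bounded, monotone, and scale-free.

Both tables are TSV files so published weight tables can be substituted.
The bundled defaults (`teguide/data/*.synthetic.tsv`) are synthetic
tables of the package's own design: penalty factors decline linearly
from 0.9 (PAM-distal position 1) to 0.1 (PAM-proximal position 20),
uniformly over nucleotide identities, reflecting the qualitative
position dependence of Cas9 mismatch tolerance; the activity model is an
identity-link 0.5 baseline with small positional nucleotide preferences.
They order guides sensibly but are not fitted to cleavage data; users
with published tables should plug them in. The design machinery consumes
scores opaquely, so swapping tables never changes the search behavior.

## Combination design

For a queried subfamily S with N copies:

* **Candidates** — every guide with ≥ 1 occurrence contained in a copy
  of S.
* **Coverage** — fraction of S's copies containing ≥ 1 occurrence of a
  combination guide. By default a copy counts only for exact
  protospacer+PAM matches (`coverage_mismatch = 0`, the conservative
  reading); a nonzero setting also credits stored neighbors within that
  distance.
* **Off-targets** — all genomic occurrences of all stored neighbors
  within k_max mismatches of any combination guide, deduplicated across
  guides (each genomic site counts once per combination), excluding
  sites inside S's own copies. Each remaining site increments exactly
  one bin: W1 if contained in any other TE copy, else W2–W5 by element
  class. TE membership outranks element class so the bins stay disjoint,
  and W1's weight (λ1 = 1e-3, an order above λ2 = 1e-4) makes TE
  off-targets the dominant penalty.
* **Score** — `Coverage − λ1·W1 − λ2·(λ3·W2 + λ4·W3 + λ5·W4 + λ6·W5)`,
  evaluated exactly, unclamped.

The greedy search ranks candidates by single-guide score, expands each
of the top `seed_beam` (default 10) seeds by repeatedly adding the guide
with the largest score increment, and stops a trace at `combo_size`
(default 3; larger sizes are allowed but combinatorial cost grows
quickly) or when no addition has a strictly positive increment.
Determinism is guaranteed by explicit tie-breaks: within an iteration,
higher coverage, then lower weighted off-target penalty, then
lexicographically smallest protospacer; between finished traces, score
descending with exact ties resolved in favor of the better-ranked seed,
so the top result is always the top seed's trace. Greedy is the
procedure, not a claimed optimum; tests verify the trace against an
independent reference implementation and, on small instances, against
exhaustive subset enumeration.

Single-copy design ranks every guide contained in one copy by its
off-copy occurrence counts at 0/1/2/3 mismatches (ascending
lexicographic on the count vector), then descending on-target score,
then sequence.

## Storage

A single-file SQLite database replaces a server deployment: `guides` +
`sites` form the main gid-keyed table (one row per occurrence, with
flanks, GC, scores, element class, TE subfamily/copy), `mismatch` holds
the neighborhood graph, and `te_copies` / `elements` persist the
annotation layers so a design query can be re-run exactly from the file
alone. Referential integrity (mismatch gids ⊆ guide gids) is checked on
every write; rebuilding from identical inputs is bit-identical except
for the metadata timestamp.

## The simulator, and what passing tests show

The simulator plants subfamilies as i.i.d.-substituted consensus copies
(rate = "divergence", optional 5′ truncation), plus decoy subfamilies
cloned from a focal consensus at a chosen divergence, and a uniform
exon/intron toy gene model, all placed without overlap on i.i.d.
background (default GC 0.41, human-like). Substitution-only evolution is
deliberate: it keeps Hamming search exactly valid, so oracle tests are
exact. The default study conditions — focal subfamily of 50 copies of a
300-bp consensus, divergence 5 %, a 10-copy decoy at 15 % consensus
divergence, 4 genes, two 25-kb chromosomes — are fixed once and used by
the test suite and the acceptance script; these sizes are desk-scale by
design, chosen so the full pipeline's behavior (coverage decay with
divergence, cross-subfamily W1 counts) is measurable in seconds.

What the simulator does *not* emulate: indels and rearrangements (real
old TEs diverge by both, so real-genome coverage at a given nominal age
will be lower than the simulated curve), nested insertions, subfamily
bursts and phylogenetic structure, GC isochores, and genome-scale
repeat counts. Passing tests therefore demonstrate algorithmic
correctness on the stated model, and the qualitative age–coverage trend
(full coverage of identical copies, monotone decay with divergence),
not genome-wide quantitative coverage of any real subfamily.

## Numerical and degenerate-input choices

Scores are plain float64 arithmetic; the score formula is evaluated
exactly and tests compare at 1e-12. Greedy stops on increments ≤ 0 (an
exactly-zero increment never adds a guide). Empty genomes scan to empty
streams; an empty index yields an empty database; a subfamily with no
candidate guides returns an empty result list; unknown copy ids and
subfamilies raise errors carrying close-match suggestions in the
library, and exit code 3 in the CLI. RNG streams in the simulator are
spawned per role (background, placement, genes, one per subfamily) in
declared order, so adding a subfamily does not perturb the others'
sequences under the same seed.

## Known limitations

Alternative PAMs (NAG off-targets), bulge-tolerant (Levenshtein)
search, non-NGG nucleases, and fitted activity models are out of scope.
The in-memory genome scan targets desk-scale genomes (tens of
megabases); whole-mammalian-genome builds would need a streaming store
path. The bundled score tables are qualitative defaults, not trained
predictors.
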