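"""Independent brute-force oracles used to check the package.

Everything here is deliberately naive and coded from the documented
contracts, not from the package's implementation: sliding-window site
enumeration, exhaustive Hamming search, linear-scan interval overlap, a
straight transcription of the greedy selection procedure, and exhaustive
subset enumeration.
"""

from collections import Counter
from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[ch] for ch in reversed(seq))


def naive_scan(chrom, seq):
    """All N20NGG sites found by sliding a 23-bp window over the forward
    sequence and its reverse complement.  Returns a set of
    (chrom, start, end, strand, protospacer, pam) tuples in forward
    coordinates."""
    seq = seq.upper()
    L = len(seq)
    out = set()
    for start in range(0, L - 22):
        w = seq[start:start + 23]
        if all(c in "ACGT" for c in w) and w[21:23] == "GG":
            out.add((chrom, start, start + 23, "+", w[:20], w[20:]))
    rev = rc(seq)
    for start in range(0, L - 22):
        w = rev[start:start + 23]
        if all(c in "ACGT" for c in w) and w[21:23] == "GG":
            fwd_start = L - (start + 23)
            out.add((chrom, fwd_start, fwd_start + 23, "-", w[:20], w[20:]))
    return out


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_mismatch_query(words, query, k):
    """(word, distance) pairs for every stored word within Hamming k."""
    return sorted(((w, hamming(w, query)) for w in words
                   if hamming(w, query) <= k), key=lambda t: (t[1], t[0]))


def brute_classify_element(chrom, start, end, promoters, exons, transcripts):
    """Linear-scan any-overlap classification with the documented
    precedence.  Interval lists contain (chrom, start, end)."""
    def overlaps(rows):
        return any(c == chrom and s < end and e > start for c, s, e in rows)
    if overlaps(promoters):
        return "promoter-TSS"
    if overlaps(exons):
        return "exon"
    if overlaps(transcripts):
        return "intron"
    return "intergenic"


def brute_containing_copies(chrom, start, end, copies):
    """All TE copies (as objects with chrom/start/end attributes) fully
    containing the interval, by linear scan."""
    return [c for c in copies
            if c.chrom == chrom and c.start <= start and end <= c.end]


# ---------------------------------------------------------------------------
# combination design oracles over abstract candidates
# ---------------------------------------------------------------------------

def combo_state(cands):
    """(covered copy_id set, {site_key: w_bin}) union of candidates."""
    cov = set()
    offs = {}
    for c in cands:
        cov |= set(c.covered)
        offs.update(dict(c.offsites))
    return cov, offs


def combo_score(cands, n_total, cfg):
    """SCORE of a candidate set, recomputed from first principles."""
    cov, offs = combo_state(cands)
    bins = Counter(offs.values())
    penalty = (cfg.lambda1 * bins[1]
               + cfg.lambda2 * (cfg.lambda3 * bins[2] + cfg.lambda4 * bins[3]
                                + cfg.lambda5 * bins[4] + cfg.lambda6 * bins[5]))
    return len(cov) / n_total - penalty


def _weighted_w(cands, n_total, cfg):
    cov, offs = combo_state(cands)
    bins = Counter(offs.values())
    return (cfg.lambda1 * bins[1]
            + cfg.lambda2 * (cfg.lambda3 * bins[2] + cfg.lambda4 * bins[3]
                             + cfg.lambda5 * bins[4] + cfg.lambda6 * bins[5]))


def _tie_key(cands, n_total, cfg, extra_proto):
    cov, _ = combo_state(cands)
    return (-combo_score(cands, n_total, cfg), -len(cov),
            _weighted_w(cands, n_total, cfg), extra_proto)


def reference_greedy(candidates, n_total, cfg):
    """Straight transcription of the documented greedy procedure: rank by
    single-guide score (ties: coverage desc, weighted off-target penalty
    asc, protospacer asc), expand each of the top seed_beam seeds by the
    best strictly-positive increment, return (gid trace, final score)
    pairs sorted by final score descending."""
    seeds = sorted(candidates,
                   key=lambda c: _tie_key([c], n_total, cfg, c.protospacer))
    seeds = seeds[:cfg.seed_beam]
    results = []
    for seed_rank, seed in enumerate(seeds):
        combo = [seed]
        current = combo_score(combo, n_total, cfg)
        while len(combo) < cfg.combo_size:
            options = []
            for cand in candidates:
                if any(cand.gid == c.gid for c in combo):
                    continue
                trial = combo + [cand]
                options.append((_tie_key(trial, n_total, cfg, cand.protospacer),
                                cand, combo_score(trial, n_total, cfg)))
            if not options:
                break
            options.sort(key=lambda t: t[0])
            _, best, best_score = options[0]
            if best_score - current <= 0:
                break
            combo.append(best)
            current = best_score
        results.append((seed_rank, [c.gid for c in combo], current))
    # score descending; equal scores keep seed order
    results.sort(key=lambda r: (-r[2], r[0]))
    return [(gids, score) for _, gids, score in results]


def exhaustive_best_trace(candidates, n_total, cfg):
    """Confirm the greedy trace by enumeration: the best single, then the
    best pair containing it, then the best triple containing that pair,
    each chosen by exhaustive scoring with the same tie-break key.
    Stops early at a non-positive increment."""
    by_gid = {c.gid: c for c in candidates}

    def best_superset(prefix_gids, size):
        pool = [c.gid for c in candidates if c.gid not in prefix_gids]
        best = None
        for extra in combinations(pool, size - len(prefix_gids)):
            gids = list(prefix_gids) + list(extra)
            cands = [by_gid[g] for g in gids]
            key = _tie_key(cands, n_total, cfg,
                           tuple(sorted(by_gid[g].protospacer for g in extra)))
            if best is None or key < best[0]:
                best = (key, gids)
        return best[1] if best else list(prefix_gids)

    trace = best_superset([], 1)
    current = combo_score([by_gid[g] for g in trace], n_total, cfg)
    while len(trace) < cfg.combo_size and len(trace) < len(candidates):
        nxt = best_superset(trace, len(trace) + 1)
        nxt_score = combo_score([by_gid[g] for g in nxt], n_total, cfg)
        if nxt_score - current <= 0:
            break
        trace, current = nxt, nxt_score
    return trace, current
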