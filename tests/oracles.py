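"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/incremental code paths:
the repeat oracle enumerates substring pairs with a character-loop Hamming
count, and the clustering oracle materializes the full all-pairs identity
matrix before simulating the greedy assignment exhaustively.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    """Hamming distance if <= limit else None; 'N' never matches."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return None
    return mm


def brute_force_repeats(
    genome: str,
    trnas,
    min_len: int = 16,
    max_len: int = 20,
    max_mismatch: int = 1,
    max_span: int = 200_000,
    win_in: int = 25,
    win_past: int = 5,
):
    """Enumerate every anchored direct-repeat pair satisfying the scan
    constraints, then collapse per tRNA by (fewest mismatches, longest,
    smallest reading-order distal start) keeping non-overlapping distal
    spans.  Returns tuples (trna_id, anchor_span, distal_span, length,
    mismatches, strand) in genome coordinates.
    """
    results = []
    for trna in trnas:
        if trna.strand == "+":
            seq = genome
            t_end = trna.end
            def to_genome(span):
                return span
        else:
            seq = _revcomp(genome)
            t_end = len(genome) - trna.start
            def to_genome(span):
                return (len(genome) - span[1], len(genome) - span[0])

        raw = []
        for k in range(min_len, max_len + 1):
            for s0 in range(max(0, t_end - win_in), min(len(seq) - k, t_end + win_past - 1) + 1):
                anchor = seq[s0: s0 + k]
                d_lo = max(t_end, s0 + k)
                d_hi = min(len(seq) - k, t_end + max_span)
                for d in range(d_lo, d_hi + 1):
                    mm = _hamming_leq(anchor, seq[d: d + k], max_mismatch)
                    if mm is not None:
                        raw.append((mm, -k, d, s0, k))
        kept = []
        for mm, neg_k, d, s0, k in sorted(raw):
            if any(d < kd + kk and kd < d + k for (_, _, kd, _, kk) in kept):
                continue
            kept.append((mm, neg_k, d, s0, k))
        for mm, _, d, s0, k in kept:
            results.append(
                (
                    trna.gene_id,
                    to_genome((s0, s0 + k)),
                    to_genome((d, d + k)),
                    k,
                    mm,
                    trna.strand,
                )
            )
    return sorted(results)


def brute_force_greedy_clusters(
    sequences: dict[str, str],
    identity_threshold: float,
    coverage_threshold: float,
    identity_fn,
):
    """Simulate the greedy assignment on a fully materialized all-pairs
    matrix (identity, coverage_a, coverage_b from ``identity_fn``)."""
    ids = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    pair = {}
    for i, a in enumerate(ids):
        for b in ids:
            if a != b:
                pair[(a, b)] = identity_fn(sequences[a], sequences[b])
    reps: list[str] = []
    assign: dict[str, str] = {}
    for sid in ids:
        home = None
        for rep in reps:
            ident, cov_a, cov_b = pair[(sid, rep)]
            if (
                ident >= identity_threshold
                and cov_a >= coverage_threshold
                and cov_b >= coverage_threshold
            ):
                home = rep
                break
        if home is None:
            reps.append(sid)
            assign[sid] = sid
        else:
            assign[sid] = home
    return assign
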