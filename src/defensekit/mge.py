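"""Detection of tRNA-anchored, direct-repeat-flanked integrated elements.

Site-specific integration into a tRNA (or tmRNA) gene regenerates the
integration site as two short direct repeats (DRs), one overlapping the
tRNA 3' end (attL/attR analogs) and one at the far boundary of the inserted
element.  The scanner looks, for every tRNA, at an anchor window spanning
the last 25 nt of the gene plus 5 nt past its 3' end, and searches
downstream (in the tRNA's reading direction) for a second, same-orientation
copy of any 16-20 nt window k-mer within 200 kb, allowing at most one
substitution (Hamming distance; no indels).

Hits describing the same boundary are collapsed deterministically, keeping
the hit with the fewest mismatches, then the longest repeat, then the
smallest distal start.  Preferring perfect repeats over longer one-mismatch
extensions makes the reported boundary the maximal exact core of the
integration site rather than an arbitrary fuzzy extension of it.

Element calls carry the genes fully contained between the repeat copies as
cargo, and are classified as predicted-active (intact integrase plus an
excisionase or rolling-circle replication initiator among the cargo),
immobilized (integrase absent, or present only as pseudogene/fragment), or
unclassified, by a configurable keyword vocabulary over the gene products.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .config import DEFAULTS
from .io import GeneRecord, GeneTable

logger = logging.getLogger("defensekit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RE = re.compile(r"^[ACGTN]*$")

# byte codes; genome 'N' and pattern 'N' use different codes so N never
# matches anything, including another N
_GENOME_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255}
_PATTERN_N = 254


@dataclass(frozen=True)
class RepeatHit:
    """A direct-repeat pair anchored at a tRNA, in genome coordinates."""

    trna_id: str
    anchor_span: tuple[int, int]
    distal_span: tuple[int, int]
    length: int
    mismatches: int
    strand: str  # strand of the anchoring tRNA

    def element_interval(self) -> tuple[int, int]:
        """Genome interval between (and excluding) the two repeat copies."""
        left, right = sorted([self.anchor_span, self.distal_span])
        return left[1], right[0]


@dataclass(frozen=True)
class ElementCall:
    element_id: str
    replicon_id: str
    span: tuple[int, int]
    anchor_repeat: tuple[int, int]
    distal_repeat: tuple[int, int]
    trna_id: str
    strand: str
    repeat_length: int
    mismatches: int
    cargo_genes: tuple[str, ...]
    mobility: str = "unclassified"
    evidence: tuple[tuple[str, str, str], ...] = ()  # (role, gene_id, keyword)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str, as_pattern: bool = False) -> np.ndarray:
    """Encode ACGTN to byte codes for vectorized Hamming comparison."""
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _GENOME_CODES.items():
        table[ord(base)] = code
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if as_pattern:
        arr = arr.copy()
        arr[arr == 255] = _PATTERN_N
    return arr


def hamming_scan(
    genome_codes: np.ndarray, pattern: np.ndarray, max_mismatch: int,
    start: int = 0, stop: int | None = None,
) -> list[tuple[int, int]]:
    """All positions in ``genome_codes[start:stop+k]`` where ``pattern``
    occurs with <= ``max_mismatch`` substitutions; returns (pos, mismatches).
    """
    k = len(pattern)
    stop = len(genome_codes) - k if stop is None else min(stop, len(genome_codes) - k)
    if stop < start:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(
        genome_codes[start: stop + k], k
    )
    mism = (windows != pattern).sum(axis=1)
    idx = np.nonzero(mism <= max_mismatch)[0]
    return [(int(start + i), int(mism[i])) for i in idx]


def _rank_key(hit: RepeatHit, reading_distal_start: int) -> tuple:
    return (hit.mismatches, -hit.length, reading_distal_start)


def _scan_one_trna_plus(
    genome_codes: np.ndarray,
    trna: GeneRecord,
    trna_start: int,
    trna_end: int,
    *,
    min_len: int,
    max_len: int,
    max_mismatch: int,
    max_span: int,
    win_in: int,
    win_past: int,
    bidirectional: bool,
) -> list[tuple[tuple[int, int], tuple[int, int], int, int]]:
    """Plus-strand geometry: anchor window at the 3' end (= ``trna_end``),
    distal copies downstream.  Returns (anchor_span, distal_span, k, mm)
    tuples in the local (plus) coordinate system."""
    length = len(genome_codes)
    out = []
    for k in range(min_len, max_len + 1):
        lo = max(0, trna_end - win_in)
        hi = min(length - k, trna_end + win_past - 1)
        for s0 in range(lo, hi + 1):
            pattern = genome_codes[s0: s0 + k].copy()
            pattern[pattern == 255] = _PATTERN_N
            d_lo = max(trna_end, s0 + k)
            d_hi = min(length - k, trna_end + max_span)
            for d, mm in hamming_scan(genome_codes, pattern, max_mismatch, d_lo, d_hi):
                out.append(((s0, s0 + k), (d, d + k), k, mm))
            if bidirectional:
                u_lo = max(0, trna_start - max_span)
                u_hi = min(s0 - k, trna_start - k)
                for d, mm in hamming_scan(
                    genome_codes, pattern, max_mismatch, u_lo, u_hi
                ):
                    out.append(((s0, s0 + k), (d, d + k), k, mm))
    return out


def _collapse(raw_hits: list[RepeatHit], reading_starts: list[int]) -> list[RepeatHit]:
    """Collapse nested/overlapping hits at one tRNA: rank by fewest
    mismatches, then longest, then smallest distal start (reading order);
    keep hits whose distal spans do not overlap an already-kept hit's."""
    order = sorted(
        range(len(raw_hits)),
        key=lambda i: _rank_key(raw_hits[i], reading_starts[i]),
    )
    kept: list[RepeatHit] = []
    for i in order:
        hit = raw_hits[i]
        lo, hi = hit.distal_span
        if any(lo < k.distal_span[1] and k.distal_span[0] < hi for k in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.distal_span)
    return kept


def find_trna_anchored_repeats(
    genome: str,
    trnas: Sequence[GeneRecord],
    min_len: int = DEFAULTS["mge"]["min_repeat_len"],
    max_len: int = DEFAULTS["mge"]["max_repeat_len"],
    max_mismatch: int = DEFAULTS["mge"]["max_mismatch"],
    max_span: int = DEFAULTS["mge"]["max_span"],
    anchor_window_in_trna: int = DEFAULTS["mge"]["anchor_window_in_trna"],
    anchor_window_past_end: int = DEFAULTS["mge"]["anchor_window_past_end"],
    bidirectional: bool = DEFAULTS["mge"]["bidirectional"],
) -> list[RepeatHit]:
    """Find direct-repeat pairs anchored at tRNA/tmRNA 3' ends.

    For each tRNA the anchor window is the last ``anchor_window_in_trna`` nt
    of the gene extended ``anchor_window_past_end`` nt past its 3' end
    (strand-aware).  Every k-mer (``min_len <= k <= max_len``) starting in
    the window is searched downstream of the 3' end, in the tRNA's reading
    direction, up to ``max_span``, for same-strand occurrences within
    ``max_mismatch`` substitutions.  Hits are collapsed per tRNA
    (fewest mismatches, longest, smallest distal start) and returned in
    genome coordinate order.
    """
    genome = genome.upper()
    if not _VALID_RE.match(genome):
        raise ValueError("genome must contain only A, C, G, T, N")
    length = len(genome)
    fwd_codes = encode_sequence(genome)
    rev_codes = encode_sequence(reverse_complement(genome))

    kwargs = dict(
        min_len=min_len,
        max_len=max_len,
        max_mismatch=max_mismatch,
        max_span=max_span,
        win_in=anchor_window_in_trna,
        win_past=anchor_window_past_end,
        bidirectional=bidirectional,
    )
    all_hits: list[RepeatHit] = []
    for trna in trnas:
        if not (0 <= trna.start < trna.end <= length):
            raise ValueError(
                f"tRNA {trna.gene_id} at [{trna.start}, {trna.end}) outside "
                f"genome of length {length}"
            )
        if trna.strand == "+":
            raw = _scan_one_trna_plus(fwd_codes, trna, trna.start, trna.end, **kwargs)
            hits = [
                RepeatHit(trna.gene_id, a, d, k, mm, "+")
                for a, d, k, mm in raw
            ]
            reading_starts = [h.distal_span[0] for h in hits]
        else:
            # run the plus-strand geometry on the reverse complement, then
            # map spans back: rc position p of length k <-> genome
            # [length - p - k, length - p)
            rc_start, rc_end = length - trna.end, length - trna.start
            raw = _scan_one_trna_plus(rev_codes, trna, rc_start, rc_end, **kwargs)
            hits = []
            reading_starts = []
            for a, d, k, mm in raw:
                anchor = (length - a[1], length - a[0])
                distal = (length - d[1], length - d[0])
                hits.append(RepeatHit(trna.gene_id, anchor, distal, k, mm, "-"))
                reading_starts.append(d[0])
        all_hits.extend(_collapse(hits, reading_starts))
    all_hits.sort(key=lambda h: (min(h.anchor_span[0], h.distal_span[0]), h.distal_span))
    return all_hits


def call_elements(
    hits: Sequence[RepeatHit],
    genes: GeneTable,
    max_span: int = DEFAULTS["mge"]["max_span"],
) -> list[ElementCall]:
    """Turn repeat hits into element calls with cargo genes.

    The element span is the interval strictly between the two repeat copies
    (both copies are reported separately); cargo genes are those fully
    contained in the span.  Overlapping candidate spans are resolved
    greedily, longest span first, so at most one element covers any region.
    """
    candidates = []
    for hit in hits:
        lo, hi = hit.element_interval()
        if hi <= lo or hi - lo > max_span:
            continue
        cargo = tuple(
            g.gene_id
            for g in genes.genes
            if g.start >= lo and g.end <= hi and g.gene_id != hit.trna_id
        )
        candidates.append((hit, (lo, hi), cargo))
    candidates.sort(key=lambda c: (-(c[1][1] - c[1][0]), c[1][0], c[0].distal_span))
    kept: list[ElementCall] = []
    for hit, (lo, hi), cargo in candidates:
        if any(lo < c.span[1] and c.span[0] < hi for c in kept):
            continue
        kept.append(
            ElementCall(
                element_id=f"elem_{hit.trna_id}_{lo}",
                replicon_id=genes.replicon_id,
                span=(lo, hi),
                anchor_repeat=hit.anchor_span,
                distal_repeat=hit.distal_span,
                trna_id=hit.trna_id,
                strand=hit.strand,
                repeat_length=hit.length,
                mismatches=hit.mismatches,
                cargo_genes=cargo,
            )
        )
    kept.sort(key=lambda c: c.span)
    return kept


# ---------------------------------------------------------------------------
# Mobility classification
# ---------------------------------------------------------------------------


def _compile_vocab(keywords: Iterable[str]) -> list[tuple[str, re.Pattern]]:
    return [
        (kw, re.compile(r"\b" + re.escape(kw) + r"\b", re.IGNORECASE))
        for kw in keywords
    ]


def classify_mobility(
    call: ElementCall,
    genes: GeneTable,
    integrase_keywords: Sequence[str] = tuple(DEFAULTS["mge"]["integrase_keywords"]),
    excisionase_keywords: Sequence[str] = tuple(DEFAULTS["mge"]["excisionase_keywords"]),
    replication_keywords: Sequence[str] = tuple(DEFAULTS["mge"]["replication_keywords"]),
) -> ElementCall:
    """Classify an element as predicted_active, immobilized, or unclassified.

    predicted_active: an intact (non-pseudo) integrase/recombinase plus an
    excisionase or rolling-circle replication initiator among the cargo.
    immobilized: no integrase at all, or integrase present only as
    pseudogenes/fragments — the vestige of the delivering recombinase.
    Everything else is unclassified.  Matching is case-insensitive,
    whole-word, over the cargo gene product annotations.
    """
    vocab = {
        "integrase": _compile_vocab(integrase_keywords),
        "excisionase": _compile_vocab(excisionase_keywords),
        "replication": _compile_vocab(replication_keywords),
    }
    by_id = {g.gene_id: g for g in genes.genes}
    evidence: list[tuple[str, str, str]] = []
    intact_integrase = pseudo_integrase = False
    has_excisionase = has_rep = False
    for gid in call.cargo_genes:
        gene = by_id[gid]
        for role, patterns in vocab.items():
            for kw, pat in patterns:
                if pat.search(gene.product):
                    evidence.append((role, gid, kw))
                    if role == "integrase":
                        if gene.is_pseudo:
                            pseudo_integrase = True
                        else:
                            intact_integrase = True
                    elif role == "excisionase" and not gene.is_pseudo:
                        has_excisionase = True
                    elif role == "replication" and not gene.is_pseudo:
                        has_rep = True
                    break
    if intact_integrase and (has_excisionase or has_rep):
        mobility = "predicted_active"
    elif not intact_integrase:
        mobility = "immobilized"
    else:
        mobility = "unclassified"
    return replace(call, mobility=mobility, evidence=tuple(evidence))
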