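"""Defense-island deduplication and genome-neighborhood extraction.

Islands arrive as annotated records (defense-system detection itself is out
of scope here).  Deduplication proceeds in three steps:

1. cluster the ORFs adjacent to each island into protein families by greedy
   incremental clustering at >= 90% global-alignment identity over >= 80%
   mutual coverage;
2. drop islands closer than 10 ORFs to a contig end (their context is
   truncated and cannot be compared);
3. group islands whose combined gene content (defense genes plus adjacent
   ORF families) differs by at most three elements, taking connected
   components of that relation (single linkage).

Identity is defined over a global alignment (BLOSUM62, gap open 11 /
extend 1) as matches divided by alignment columns, gaps counted as columns.
This is a reproducible approximation of word-based clustering heuristics,
not an emulation of any particular tool.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULTS, log_filter
from .io import GeneRecord, GeneTable

logger = logging.getLogger("defensekit")

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class FamilyAssignment:
    """member_id -> family_id map plus the representative of each family."""

    family_of: dict[str, str]
    representatives: dict[str, str]  # family_id -> representative member_id

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member, fam in self.family_of.items():
            out.setdefault(fam, []).append(member)
        return {k: sorted(v) for k, v in out.items()}


@dataclass
class IslandRecord:
    """A defense island and its genomic context.

    ``orfs_from_contig_end`` is the (left, right) number of ORFs between the
    island and the nearer contig end on each side; a bare int is accepted
    and applied to both sides.
    """

    island_id: str
    replicon_id: str
    span: tuple[int, int]
    defense_genes: tuple[str, ...]
    context_families: frozenset[str]
    orfs_from_contig_end: tuple[int, int]

    def __post_init__(self) -> None:
        if isinstance(self.orfs_from_contig_end, int):
            self.orfs_from_contig_end = (
                self.orfs_from_contig_end,
                self.orfs_from_contig_end,
            )
        if min(self.orfs_from_contig_end) < 0:
            raise ValueError(f"{self.island_id}: negative contig-end distance")
        self.defense_genes = tuple(self.defense_genes)
        self.context_families = frozenset(self.context_families)

    def content(self) -> frozenset[str]:
        """Combined gene content: defense genes plus adjacent ORF families."""
        return frozenset(self.defense_genes) | self.context_families


@dataclass(frozen=True)
class IslandFamily:
    family_id: str
    members: tuple[str, ...]
    consensus_content: frozenset[str]


@dataclass(frozen=True)
class Neighborhood:
    """Genes around an anchor, ordered 5'->3' along the anchor's strand."""

    anchor_id: str
    genes: tuple[GeneRecord, ...]
    offsets: tuple[int, ...]  # signed positions relative to the anchor


# ---------------------------------------------------------------------------
# Protein-family clustering
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def alignment_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None
                       ) -> tuple[float, float, float]:
    """Global-alignment identity and mutual coverage of two protein sequences.

    Returns ``(identity, coverage_a, coverage_b)`` where identity is
    matches / alignment columns (gap columns included) and coverage_x is the
    fraction of x aligned residue-to-residue.
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    identities, mismatches = aln.counts().identities, aln.counts().mismatches
    aligned_cols = identities + mismatches
    gaps = aln.length - aligned_cols
    identity = identities / aln.length if aln.length else 0.0
    return identity, aligned_cols / len(a), aligned_cols / len(b)


def cluster_protein_families(
    sequences: Mapping[str, str],
    identity_threshold: float = DEFAULTS["islands"]["identity_threshold"],
    coverage_threshold: float = DEFAULTS["islands"]["coverage_threshold"],
) -> FamilyAssignment:
    """Greedy incremental clustering of protein sequences into families.

    Sequences are processed longest first (ties by id, lexicographic); each
    joins the first existing representative it matches at
    identity >= ``identity_threshold`` with coverage >= ``coverage_threshold``
    of *both* sequences, otherwise it founds a new family named after itself.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    bad = sorted(
        sid for sid, seq in sequences.items() if not _AA_RE.match(seq.upper())
    )
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence(s): {bad}")

    aligner = _make_aligner()
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    reps: list[str] = []  # representative ids, in founding order
    family_of: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid].upper()
        placed = False
        for rep in reps:
            ident, cov_a, cov_b = alignment_identity(
                seq, sequences[rep].upper(), aligner
            )
            if (
                ident >= identity_threshold
                and cov_a >= coverage_threshold
                and cov_b >= coverage_threshold
            ):
                family_of[sid] = rep
                placed = True
                break
        if not placed:
            reps.append(sid)
            family_of[sid] = sid
    logger.info(
        "clustered %d sequences into %d families (identity>=%.2f, coverage>=%.2f)",
        len(sequences), len(reps), identity_threshold, coverage_threshold,
    )
    return FamilyAssignment(
        family_of=family_of, representatives={rep: rep for rep in reps}
    )


# ---------------------------------------------------------------------------
# Island filtering, neighborhoods, grouping
# ---------------------------------------------------------------------------


def filter_contig_edge_islands(
    islands: Sequence[IslandRecord],
    min_flank_orfs: int = DEFAULTS["islands"]["min_flank_orfs"],
) -> list[IslandRecord]:
    """Keep only islands at least ``min_flank_orfs`` ORFs from both contig
    ends."""
    kept = [
        isl for isl in islands if min(isl.orfs_from_contig_end) >= min_flank_orfs
    ]
    log_filter("filter_contig_edge_islands", min_flank_orfs, len(islands), len(kept))
    return kept


def extract_neighborhood(
    gene_table: GeneTable,
    anchor_gene_id: str,
    flank: int = DEFAULTS["islands"]["neighborhood_flank"],
) -> Neighborhood:
    """Up to ``flank`` genes on each side of an anchor, in the anchor's
    reading direction.

    For a minus-strand anchor the gene order and the offset signs are
    reversed so that the anchor's 5'->3' reading runs left to right.  Flanks
    truncated by a contig end are simply shorter.
    """
    idx = gene_table.index_of(anchor_gene_id)
    anchor = gene_table.genes[idx]
    lo = max(0, idx - flank)
    hi = min(len(gene_table.genes), idx + flank + 1)
    genes = list(gene_table.genes[lo:hi])
    offsets = [i - idx for i in range(lo, hi)]
    if anchor.strand == "-":
        genes.reverse()
        offsets = [-o for o in reversed(offsets)]
    return Neighborhood(anchor_id=anchor_gene_id, genes=tuple(genes),
                        offsets=tuple(offsets))


def content_difference(a: IslandRecord, b: IslandRecord) -> int:
    """Gene-content difference: size of the symmetric set difference of the
    islands' combined content (presence/absence; copy number ignored)."""
    return len(a.content() ^ b.content())


def group_island_families(
    islands: Sequence[IslandRecord],
    max_diff: int = DEFAULTS["islands"]["max_content_diff"],
) -> list[IslandFamily]:
    """Group islands by shared gene content, allowing up to ``max_diff``
    differences.

    Islands whose content differs by <= ``max_diff`` elements are linked;
    island families are the connected components of that graph (single
    linkage), so chains of small differences merge.  Family ids are
    deterministic: the smallest member island_id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(isl.island_id for isl in islands)
    by_id = {isl.island_id: isl for isl in islands}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if content_difference(by_id[a], by_id[b]) <= max_diff:
                graph.add_edge(a, b)
    families = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        consensus = frozenset.intersection(
            *[by_id[m].content() for m in members]
        )
        families.append(
            IslandFamily(
                family_id=members[0], members=members, consensus_content=consensus
            )
        )
    families.sort(key=lambda f: f.family_id)
    log_filter("group_island_families", max_diff, len(islands), len(families))
    return families


def build_island_records(
    island_orfs: Mapping[str, Sequence[str]],
    assignment: FamilyAssignment,
    defense_genes: Mapping[str, Sequence[str]] | None = None,
    flank_orfs: int = 100,
) -> list[IslandRecord]:
    """Convenience: turn per-island ORF lists plus a family assignment into
    IslandRecords (synthetic spans; used by the deduplication pipeline and
    the recovery tests)."""
    records = []
    for i, (island_id, orfs) in enumerate(sorted(island_orfs.items())):
        fams = frozenset(assignment.family_of[o] for o in orfs)
        records.append(
            IslandRecord(
                island_id=island_id,
                replicon_id=island_id,
                span=(0, 1000),
                defense_genes=tuple(
                    defense_genes.get(island_id, ()) if defense_genes else ()
                ),
                context_families=fams,
                orfs_from_contig_end=(flank_orfs, flank_orfs),
            )
        )
    return records
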