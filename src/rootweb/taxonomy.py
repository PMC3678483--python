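"""Two-tier reference databases and lowest-common-ancestor (LCA) taxonomy.

OTUs are identified against two nested reference subsets: a "genus" database
(records identified to genus or species) and a "class" database (records
identified to class or below).  Each query receives three provisional
lineages -- strict LCA on the genus tier, strict LCA on the class tier, and a
relaxed LCA on the genus tier that tolerates 10% discordant homologs -- which
are merged with priority LCA/genus > LCA/class > relaxed-LCA/genus, subject to
ancestor consistency.  The relaxed variant exists because a single
misannotated database record otherwise truncates an identification.

Homolog search uses the same alignment-identity kernel as OTU clustering: all
records within a fixed identity window below the best hit, above an absolute
identity floor, capped in number.  (An E-value model is out of scope.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .alignment import kmer_set, kmer_share, pairwise_identity

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

IDENTITY_DROP = 0.03
MAX_HITS = 50
MIN_HIT_IDENTITY = 0.80
RELAXED_TOLERANCE = 0.10
_EPS = 1e-9

Lineage = Tuple[str, str, str, str, str, str, str]
EMPTY_LINEAGE: Lineage = ("",) * 7


def lineage_depth(lineage: Sequence[str]) -> int:
    """Number of contiguously assigned ranks from kingdom down."""
    depth = 0
    for name in lineage:
        if not name:
            break
        depth += 1
    return depth


@dataclass
class ReferenceRecord:
    """A reference sequence with a (possibly truncated) 7-rank lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self):
        self.lineage = tuple(self.lineage)
        if len(self.lineage) != 7:
            raise ValueError(f"record {self.id}: lineage must have 7 ranks")
        seen_empty = False
        for name in self.lineage:
            if not name:
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"record {self.id}: lineage has a gap (non-contiguous ranks)"
                )

    def rank(self, rank: str) -> str:
        return self.lineage[_RANK_INDEX[rank]]


@dataclass
class TieredDatabase:
    """Reference records restricted to those annotated at the tier rank."""

    tier: str
    records: Dict[str, ReferenceRecord]
    _kmers: Dict[str, frozenset] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.tier not in ("genus", "class"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if not self._kmers:
            self._kmers = {rid: kmer_set(rec.sequence)
                           for rid, rec in self.records.items()}


def build_tier_db(records: Iterable[ReferenceRecord], tier: str) -> TieredDatabase:
    """Keep exactly the records whose lineage reaches the tier rank."""
    if tier not in ("genus", "class"):
        raise ValueError(f"unknown tier {tier!r}")
    idx = _RANK_INDEX[tier]
    kept = {r.id: r for r in records if r.lineage[idx]}
    return TieredDatabase(tier=tier, records=kept)


@dataclass
class HomologSet:
    """Ranked homologs of one query: (record id, identity), identity desc."""

    query_id: str
    hits: List[Tuple[str, float]]


def find_homologs(
    query: str,
    db: TieredDatabase,
    query_id: str = "query",
    identity_drop: float = IDENTITY_DROP,
    max_hits: int = MAX_HITS,
    min_identity: float = MIN_HIT_IDENTITY,
) -> HomologSet:
    """All records within ``identity_drop`` of the best identity.

    Hits below ``min_identity`` are never reported; at most ``max_hits`` are
    kept.  An empty hit set is a legitimate outcome.
    """
    if not db.records:
        raise ValueError("empty reference database")
    qk = kmer_set(query)
    scored: List[Tuple[float, str]] = []
    for rid, rec in db.records.items():
        # identity floor 0.80 implies a k-mer containment well above 0.02
        if kmer_share(qk, db._kmers[rid]) < 0.02:
            continue
        ident = pairwise_identity(query, rec.sequence)
        if ident >= min_identity:
            scored.append((ident, rid))
    if not scored:
        return HomologSet(query_id=query_id, hits=[])
    scored.sort(key=lambda t: (-t[0], t[1]))
    best = scored[0][0]
    floor = max(best - identity_drop, min_identity)
    hits = [(rid, ident) for ident, rid in scored if ident >= floor - _EPS]
    return HomologSet(query_id=query_id, hits=hits[:max_hits])


def _consensus_lineage(
    hits: HomologSet, db: TieredDatabase, tolerance: float
) -> Lineage:
    """Rank-by-rank majority lineage; truncate at the first failing rank.

    At each rank only hits carrying the rank are counted (absence of
    annotation is not evidence of conflict); the majority name is assigned
    when its support is >= (1 - tolerance), inclusive.  tolerance=0
    degenerates to the strict LCA (unanimity) rule.
    """
    out: List[str] = []
    records = [db.records[rid] for rid, _ in hits.hits]
    for ri in range(7):
        names = [r.lineage[ri] for r in records if r.lineage[ri]]
        if not names:
            break
        counts: Dict[str, int] = {}
        for n in names:
            counts[n] = counts.get(n, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        name, support = top[0]
        # A tied majority is impossible here: two names each with support
        # >= (1 - tolerance) * n would need tolerance >= 0.5.
        if support < (1.0 - tolerance) * len(names) - _EPS:
            break
        out.append(name)
    return tuple(out) + ("",) * (7 - len(out))


def strict_lca(hits: HomologSet, db: TieredDatabase) -> Lineage:
    """Deepest rank at which all hits carrying that rank agree."""
    if not hits.hits:
        return EMPTY_LINEAGE
    return _consensus_lineage(hits, db, tolerance=0.0)


def relaxed_lca(
    hits: HomologSet, db: TieredDatabase, tolerance: float = RELAXED_TOLERANCE
) -> Lineage:
    """LCA tolerating a fraction ``tolerance`` of discordant homologs."""
    if not (0.0 <= tolerance < 0.5):
        raise ValueError("tolerance must be in [0, 0.5)")
    if not hits.hits:
        return EMPTY_LINEAGE
    return _consensus_lineage(hits, db, tolerance=tolerance)


@dataclass
class LineageAssignment:
    """Merged taxonomy of one OTU, with the method that produced each rank."""

    otu_id: str
    lineage: Lineage
    methods: Tuple[str, ...]  # per assigned rank: LCA/genus, LCA/class, ...
    ecotype: str = "unknown"

    @property
    def depth(self) -> int:
        return lineage_depth(self.lineage)

    def rank(self, rank: str) -> str:
        return self.lineage[_RANK_INDEX[rank]]


METHOD_LABELS = ("LCA/genus", "LCA/class", "relaxed-LCA/genus")


def merge_with_priority(
    lca_genus: Lineage,
    lca_class: Lineage,
    relaxed_genus: Lineage,
    otu_id: str = "",
) -> LineageAssignment:
    """Merge the three lineages rank by rank, with priority in listed order.

    At each rank, the highest-priority source that assigns it and whose
    ancestor ranks agree with what has already been merged wins; merging stops
    at the first rank no source can fill consistently.
    """
    sources = [
        (tuple(lca_genus), METHOD_LABELS[0]),
        (tuple(lca_class), METHOD_LABELS[1]),
        (tuple(relaxed_genus), METHOD_LABELS[2]),
    ]
    merged: List[str] = []
    methods: List[str] = []
    for ri in range(7):
        filled = False
        for lineage, label in sources:
            if not lineage[ri]:
                continue
            if lineage[:ri] != tuple(merged[:ri]):
                continue  # ancestors must match the merged prefix exactly
            merged.append(lineage[ri])
            methods.append(label)
            filled = True
            break
        if not filled:
            break
    lineage = tuple(merged) + ("",) * (7 - len(merged))
    return LineageAssignment(otu_id=otu_id, lineage=lineage, methods=tuple(methods))


ECOTYPE_LABELS = ("ectomycorrhizal", "arbuscular", "parasitic", "unknown")

# Minimal shipped ecotype lookup (taxon name, rank) -> ecotype; users extend it
# from a TSV.  Genus beats family beats phylum when several ranks match.
DEFAULT_ECOTYPE_ROWS: List[Tuple[str, str, str]] = [
    ("Russula", "genus", "ectomycorrhizal"),
    ("Lactarius", "genus", "ectomycorrhizal"),
    ("Cortinarius", "genus", "ectomycorrhizal"),
    ("Tomentella", "genus", "ectomycorrhizal"),
    ("Amanita", "genus", "ectomycorrhizal"),
    ("Boletus", "genus", "ectomycorrhizal"),
    ("Cenococcum", "genus", "ectomycorrhizal"),
    ("Russulaceae", "family", "ectomycorrhizal"),
    ("Glomeromycota", "phylum", "arbuscular"),
]


@dataclass
class EcotypeTable:
    """Taxon-name -> ecotype lookup, resolved at the most specific rank."""

    by_rank: Dict[str, Dict[str, str]]

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple[str, str, str]]) -> "EcotypeTable":
        by_rank: Dict[str, Dict[str, str]] = {}
        for taxon, rank, ecotype in rows:
            if rank not in _RANK_INDEX:
                raise ValueError(f"unknown rank {rank!r} in ecotype table")
            by_rank.setdefault(rank, {})[taxon] = ecotype
        return cls(by_rank=by_rank)

    @classmethod
    def default(cls) -> "EcotypeTable":
        return cls.from_rows(DEFAULT_ECOTYPE_ROWS)

    @classmethod
    def from_tsv(cls, path) -> "EcotypeTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_rows(df[["taxon", "rank", "ecotype"]].itertuples(index=False))


def assign_ecotype(assignment: LineageAssignment, table: EcotypeTable) -> str:
    """Most-specific matching taxon name wins; no match -> "unknown"."""
    for ri in range(6, -1, -1):
        name = assignment.lineage[ri]
        if not name:
            continue
        rank = RANKS[ri]
        eco = table.by_rank.get(rank, {}).get(name)
        if eco is not None:
            return eco
    return "unknown"
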