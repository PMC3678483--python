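"""Two-stage consensus clustering into OTUs, chimera flagging and table filters.

Stage 1 clusters reads within each sample at 97% identity; stage 2 clusters
the resulting within-sample consensus sequences across samples (97% for the
fungal ITS2 marker, 99.8% for the host rbcL marker).  Both stages use greedy
abundance-ordered centroid clustering (the standard metabarcoding stand-in
for overlap assembly at the same identity contract): sequences are visited in
decreasing abundance, join the best existing centroid at >= the threshold, or
found a new cluster.  Cluster consensus is the weighted column-majority of
members projected onto centroid coordinates, with IUPAC codes at tied columns.

Chimera flagging follows a two-parent model: a cluster is flagged when a
prefix/suffix split over two more-abundant same-sample clusters explains its
consensus better than any single parent, with

    score = (chimeric identity - best single identity) / (1 - best single)

reported at score >= 0.1.  Profiles are positional (ungapped), matching the
substitution-dominated error model of the read simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import align_pairs, encode, kmer_set, kmer_share, pairwise_identity
from .reads import TaggedRead

ITS_IDENTITY = 0.97
RBCL_IDENTITY = 0.998
HOST_MIN_IDENTITY = 0.998
MIN_READS_PER_OTU = 5
MIN_SAMPLE_READS = 100

_IUPAC_FOR = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
_BASES = "ACGT"


@dataclass
class SeqCluster:
    """A cluster of sequences with a column-majority consensus."""

    members: List[str]
    consensus: str
    size: int
    sample_id: Optional[str] = None


class _Centroid:
    __slots__ = ("seq", "enc", "kmers", "votes", "members", "size")

    def __init__(self, seq: str, weight: int, members: List[str]):
        self.seq = seq
        self.enc = encode(seq)
        self.kmers = kmer_set(seq)
        # votes[i] = weighted counts for A, C, G, T, gap at centroid column i
        self.votes = np.zeros((len(seq), 5), dtype=np.float64)
        self.votes[np.arange(len(seq)), np.minimum(self.enc, 4)] += weight
        self.members = list(members)
        self.size = weight

    def add(self, seq_enc: np.ndarray, weight: int, members: List[str],
            pairs_a: np.ndarray, pairs_b: np.ndarray) -> None:
        # pairs_a indexes the centroid when the centroid was the first argument
        self.votes[pairs_a, np.minimum(seq_enc[pairs_b], 4)] += weight
        if pairs_a.size:
            covered = np.zeros(len(self.seq), dtype=bool)
            covered[pairs_a] = True
            lo, hi = pairs_a.min(), pairs_a.max()
            gaps = np.nonzero(~covered[lo : hi + 1])[0] + lo
            self.votes[gaps, 4] += weight
        self.members.extend(members)
        self.size += weight

    def consensus(self) -> str:
        v = self.votes
        top = v.max(axis=1)
        winners = v == top[:, None]
        base_winners = winners[:, :4]
        n_base = base_winners.sum(axis=1)
        gap_majority = winners[:, 4] & (n_base == 0)  # strict gap win: drop
        # fast path: unique base winner
        idx = np.argmax(base_winners, axis=1)
        chars = np.array(list(_BASES))[idx]
        ties = np.nonzero(n_base > 1)[0]
        for i in ties:  # rare: tied columns get an IUPAC ambiguity code
            bases = frozenset(_BASES[w] for w in np.nonzero(base_winners[i])[0])
            chars[i] = _IUPAC_FOR[bases]
        return "".join(chars[~gap_majority])


def _greedy_cluster(
    items: Sequence[Tuple[str, int, List[str]]],
    min_identity: float,
    kmer_cutoff: float = 0.25,
) -> List[_Centroid]:
    """Greedy centroid clustering of (sequence, weight, member_ids) items.

    Items are visited in decreasing weight (ties broken lexicographically by
    sequence, for determinism).  Each item joins the best centroid whose
    identity is >= min_identity, else founds a new centroid.
    """
    order = sorted(items, key=lambda it: (-it[1], it[0]))
    centroids: List[_Centroid] = []
    for seq, weight, members in order:
        enc = encode(seq)
        kmers = kmer_set(seq)
        best_i = -1
        best_id = min_identity
        best_pairs = None
        for i, cen in enumerate(centroids):
            if kmer_share(kmers, cen.kmers) < kmer_cutoff:
                continue
            # Ungapped (positional) identity is a valid-alignment lower bound
            # and exact for substitution-only divergence; it short-circuits
            # the DP for the common case of a read matching its template.
            ov = min(len(enc), len(cen.enc))
            matches = int(np.count_nonzero(enc[:ov] == cen.enc[:ov]))
            ident = matches / ov
            if ident >= min_identity:
                pa = pb = None  # positional: pairs are arange(ov)
            else:
                matches, cols, pa, pb = align_pairs(cen.enc, enc)
                ident = matches / cols if cols else 0.0
            if ident > best_id or (ident == best_id and best_i < 0):
                best_i, best_id, best_pairs = i, ident, (pa, pb)
        if best_i < 0:
            centroids.append(_Centroid(seq, weight, members))
        else:
            cen = centroids[best_i]
            pa, pb = best_pairs
            if pa is None:
                ov = min(len(enc), len(cen.enc))
                pa = pb = np.arange(ov, dtype=np.int32)
            cen.add(enc, weight, members, pa, pb)
    return centroids


def cluster_within_sample(
    reads: Sequence[TaggedRead],
    min_identity: float = ITS_IDENTITY,
    sample_id: Optional[str] = None,
) -> List[SeqCluster]:
    """Cluster one sample's reads at ``min_identity`` (default 97%)."""
    if sample_id is None and reads:
        sample_id = reads[0].sample_id
    # dereplicate identical sequences first; weight = read multiplicity
    by_seq: Dict[str, List[str]] = {}
    for r in reads:
        by_seq.setdefault(r.bases, []).append(r.id)
    items = [(seq, len(ids), ids) for seq, ids in by_seq.items()]
    cents = _greedy_cluster(items, min_identity)
    clusters = [
        SeqCluster(members=c.members, consensus=c.consensus(), size=c.size,
                   sample_id=sample_id)
        for c in cents
    ]
    clusters.sort(key=lambda c: (-c.size, c.consensus))
    return clusters


def _match_profile(child: str, parent: str) -> np.ndarray:
    """Positional (ungapped) match indicator of child vs parent, child coords."""
    n = len(child)
    prof = np.zeros(n, dtype=np.int32)
    m = min(n, len(parent))
    a = np.frombuffer(child[:m].encode(), dtype=np.uint8)
    b = np.frombuffer(parent[:m].encode(), dtype=np.uint8)
    prof[:m] = a == b
    return prof


@dataclass
class ChimeraFlag:
    cluster_index: int
    parent_indices: Tuple[int, int]
    score: float
    chimeric_identity: float
    best_single_identity: float


def flag_chimeras(
    clusters: Sequence[SeqCluster],
    min_score: float = 0.1,
    min_parent_ratio: float = 2.0,
) -> List[ChimeraFlag]:
    """Flag within-sample clusters explained by a two-parent crossover.

    Parents must come from the same sample and be at least ``min_parent_ratio``
    times more abundant than the candidate.  The candidate's parents are never
    flagged by the candidate itself (self-parenting excluded).
    """
    flags: List[ChimeraFlag] = []
    for ci, cand in enumerate(clusters):
        parent_idx = [
            pi for pi, p in enumerate(clusters)
            if pi != ci and p.size >= min_parent_ratio * cand.size
        ]
        if len(parent_idx) < 2:
            continue
        n = len(cand.consensus)
        if n == 0:
            continue
        profiles = {pi: _match_profile(cand.consensus, clusters[pi].consensus)
                    for pi in parent_idx}
        prefix = {pi: np.concatenate(([0], np.cumsum(prof)))
                  for pi, prof in profiles.items()}
        best_single = max(int(prof.sum()) for prof in profiles.values())
        best_chim = best_single
        best_pair = None
        for pi in parent_idx:
            for pj in parent_idx:
                if pi == pj:
                    continue
                # prefix from pi, suffix from pj; best over crossover k
                comb = prefix[pi][:-1] + (prefix[pj][-1] - prefix[pj][:-1])
                k = int(comb.max())
                if k > best_chim:
                    best_chim = k
                    best_pair = (pi, pj)
        if best_pair is None:
            continue
        single_id = best_single / n
        chim_id = best_chim / n
        if single_id >= 1.0:
            continue
        score = (chim_id - single_id) / (1.0 - single_id)
        if score >= min_score:
            flags.append(ChimeraFlag(ci, best_pair, score, chim_id, single_id))
    return flags


@dataclass
class OTUTable:
    """OTU x sample read-count matrix with per-OTU consensus sequences."""

    counts: pd.DataFrame  # index: otu ids, columns: sample ids
    consensus: Dict[str, str]
    flags: Dict[str, str] = field(default_factory=dict)

    @property
    def otu_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="otu_id")


def cluster_among_samples(
    consensi: Sequence[Tuple[str, str, int]],
    min_identity: float,
    otu_prefix: str = "OTU",
) -> Tuple[OTUTable, List[SeqCluster]]:
    """Cluster within-sample consensus sequences across samples into OTUs.

    ``consensi`` items are (sequence, sample_id, read_count).  Counts
    accumulate into an OTU x sample matrix; OTUs are named by decreasing
    total read count (ties broken by consensus sequence).
    """
    items = [
        (seq, count, [f"{sample}:{i}"])
        for i, (seq, sample, count) in enumerate(consensi)
    ]
    cents = _greedy_cluster(items, min_identity)
    sample_of = {f"{sample}:{i}": sample
                 for i, (seq, sample, count) in enumerate(consensi)}
    count_of = {f"{sample}:{i}": count
                for i, (seq, sample, count) in enumerate(consensi)}
    ranked = sorted(cents, key=lambda c: (-c.size, c.seq))
    samples = sorted({s for _, s, _ in consensi})
    width = max(4, len(str(len(ranked))))
    otu_ids = [f"{otu_prefix}_{i + 1:0{width}d}" for i in range(len(ranked))]
    mat = pd.DataFrame(0, index=otu_ids, columns=samples, dtype=np.int64)
    consensus = {}
    clusters = []
    for otu_id, cen in zip(otu_ids, ranked):
        cons = cen.consensus()
        consensus[otu_id] = cons
        clusters.append(SeqCluster(members=list(cen.members), consensus=cons,
                                   size=cen.size))
        for mid in cen.members:
            mat.loc[otu_id, sample_of[mid]] += count_of[mid]
    return OTUTable(counts=mat, consensus=consensus), clusters


@dataclass
class FilterReport:
    singleton_otus: List[str]
    below_min_otus: List[str]
    dropped_samples: List[str]
    singleton_reads: int
    below_min_reads: int
    dropped_sample_reads: int


def filter_otu_table(
    table: OTUTable,
    min_reads_per_otu: int = MIN_READS_PER_OTU,
    min_sample_reads: int = MIN_SAMPLE_READS,
) -> Tuple[OTUTable, FilterReport]:
    """Apply the OTU/sample filter cascade, in order:

    1. drop OTUs whose total count is 1 (singletons),
    2. drop OTUs with fewer than ``min_reads_per_otu`` reads in every sample,
    3. drop samples whose remaining total is below ``min_sample_reads``.
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    singletons = list(counts.index[totals == 1])
    counts = counts.drop(index=singletons)
    maxima = counts.max(axis=1) if len(counts) else pd.Series(dtype=np.int64)
    below = list(counts.index[maxima < min_reads_per_otu])
    below_reads = int(counts.loc[below].to_numpy().sum()) if below else 0
    counts = counts.drop(index=below)
    sample_totals = counts.sum(axis=0)
    dropped_samples = list(counts.columns[sample_totals < min_sample_reads])
    dropped_reads = int(counts[dropped_samples].to_numpy().sum()) if dropped_samples else 0
    counts = counts.drop(columns=dropped_samples)
    flags = dict(table.flags)
    flags.update({o: "singleton_removed" for o in singletons})
    flags.update({o: "below_5_read_rule" for o in below})
    filtered = OTUTable(
        counts=counts.copy(),
        consensus={o: table.consensus[o] for o in counts.index},
        flags=flags,
    )
    report = FilterReport(
        singleton_otus=singletons,
        below_min_otus=below,
        dropped_samples=dropped_samples,
        singleton_reads=len(singletons),
        below_min_reads=below_reads,
        dropped_sample_reads=dropped_reads,
    )
    return filtered, report


@dataclass
class HostAssignment:
    sample_id: str
    species: str
    identity: float
    reference_id: str


def assign_host(
    consensus: str,
    references: Sequence[Tuple[str, str, str]],
    min_identity: float = HOST_MIN_IDENTITY,
    sample_id: str = "",
) -> Optional[HostAssignment]:
    """Best-identity host match; ties and sub-threshold matches -> None.

    ``references`` items are (reference_id, species_name, sequence).
    """
    if not references:
        raise ValueError("empty host reference set")
    best: List[Tuple[str, str]] = []
    best_id = -1.0
    qk = kmer_set(consensus)
    for ref_id, species, seq in references:
        if kmer_share(qk, kmer_set(seq)) < 0.05:
            continue  # cannot possibly reach a 99.8%-level identity
        ident = pairwise_identity(consensus, seq)
        if ident > best_id:
            best_id = ident
            best = [(ref_id, species)]
        elif ident == best_id:
            best.append((ref_id, species))
    if best_id < min_identity or len(best) != 1:
        return None
    ref_id, species = best[0]
    return HostAssignment(sample_id=sample_id, species=species,
                         identity=best_id, reference_id=ref_id)
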