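"""Raw tagged pyrosequencing reads -> per-sample, per-gene filtered read sets.

The stage order mirrors a 454-era tag-encoded amplicon protocol:

1. 3' quality trimming at a minimum quality value (QV) of 20,
2. demultiplexing on exact 8-mer molecular IDs (MIDs), MID stripped,
3. gene recognition from the forward primer (IUPAC-aware), primer stripped,
4. per-gene minimum-length filter (rbcL >= 400 bp, ITS >= 150 bp),

with full read accounting along the cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

MIN_QV = 20
MID_LENGTH = 8
DEFAULT_MIN_LENGTH = {"rbcL": 400, "ITS": 150}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (e.g. duplicate MIDs)."""


class AccountingError(ValueError):
    """Read counts violate the filter-cascade arithmetic."""


@dataclass
class TaggedRead:
    """One pyrosequencing read with per-base qualities.

    ``sample_id`` and ``gene`` are filled in by demultiplexing and gene
    classification respectively.
    """

    id: str
    bases: str
    qualities: np.ndarray
    sample_id: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases and qualities differ in length")
        if len(self.qualities) and (self.qualities.min() < 0 or self.qualities.max() > 45):
            raise ValueError(f"read {self.id}: quality values outside [0, 45]")

    def __len__(self) -> int:
        return len(self.bases)


def trim_quality_tail(read: TaggedRead, min_qv: int = MIN_QV) -> TaggedRead:
    """Cut the longest terminal suffix whose running mean QV is below ``min_qv``.

    Scanning from the 3' end, the cut point is the smallest index ``i`` such
    that mean(q[i:]) < min_qv; the returned read is the prefix before it.  The
    output therefore has no suffix with mean QV below the threshold.  May
    return an empty read.
    """
    q = read.qualities
    n = len(q)
    if n == 0:
        return read
    # mean of q[i:] for every i, computed from a reversed cumulative sum
    suffix_means = np.cumsum(q[::-1]) / np.arange(1, n + 1)
    bad = np.nonzero(suffix_means[::-1] < min_qv)[0]
    if bad.size == 0:
        return read
    cut = int(bad[0])
    return replace(read, bases=read.bases[:cut], qualities=q[:cut])


def _mid_mapping(mid_table) -> Dict[str, str]:
    """Accept a mapping mid->sample or a DataFrame with sample_id/mid columns."""
    if isinstance(mid_table, pd.DataFrame):
        mids = mid_table["mid"].tolist()
        samples = mid_table["sample_id"].tolist()
        mapping = dict(zip(mids, samples))
        if len(mapping) != len(mids):
            raise ConfigError("duplicate MIDs in MID table")
    else:
        mapping = dict(mid_table)
    lengths = {len(m) for m in mapping}
    if len(lengths) > 1:
        raise ConfigError("MIDs must all have the same length")
    return mapping


def demultiplex(
    reads: Iterable[TaggedRead], mid_table, mid_length: int = MID_LENGTH
) -> Tuple[List[TaggedRead], List[TaggedRead]]:
    """Assign reads to samples by exact leading-MID match; strip the MID.

    Returns (assigned, rejected).  Every input read lands in exactly one of
    the two bins.  Exact matching only: the 8-mer tags carry no stated error
    tolerance, and the shipped MID sets keep pairwise Hamming distance >= 3 so
    a single sequencing error can never silently reassign a read.
    """
    mapping = _mid_mapping(mid_table)
    assigned: List[TaggedRead] = []
    rejected: List[TaggedRead] = []
    for read in reads:
        mid = read.bases[:mid_length]
        sample = mapping.get(mid) if len(mid) == mid_length else None
        if sample is None:
            rejected.append(read)
        else:
            assigned.append(
                replace(
                    read,
                    bases=read.bases[mid_length:],
                    qualities=read.qualities[mid_length:],
                    sample_id=sample,
                )
            )
    return assigned, rejected


def iupac_mismatches(primer: str, seq: str) -> int:
    """Hamming-style mismatch count of ``seq`` against an IUPAC primer.

    Missing positions (sequence shorter than the primer) count as mismatches;
    indels are not modelled.
    """
    mm = max(0, len(primer) - len(seq))
    for p, s in zip(primer, seq):
        if s.upper() not in IUPAC.get(p.upper(), ""):
            mm += 1
    return mm


@dataclass
class PrimerSet:
    """Forward primers keyed by gene, with a shared mismatch tolerance."""

    primers: Dict[str, str]
    tolerance: int = 2

    @classmethod
    def from_json(cls, path) -> "PrimerSet":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(primers=cfg["primers"], tolerance=cfg.get("tolerance", 2))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"primers": self.primers, "tolerance": self.tolerance}, fh, indent=1)


def classify_gene(read: TaggedRead, primer_set: PrimerSet) -> Optional[TaggedRead]:
    """Label a demultiplexed read by its best forward-primer match.

    The primer with the fewest mismatches at the expected (leading) position
    wins, provided it is within tolerance; equally good primers are ambiguous
    and the read is rejected (None).  The matched primer is stripped.
    """
    scores = {
        gene: iupac_mismatches(primer, read.bases[: len(primer)])
        for gene, primer in primer_set.primers.items()
    }
    best = min(scores.values())
    if best > primer_set.tolerance:
        return None
    winners = [g for g, s in scores.items() if s == best]
    if len(winners) != 1:
        return None
    gene = winners[0]
    plen = len(primer_set.primers[gene])
    return replace(
        read, bases=read.bases[plen:], qualities=read.qualities[plen:], gene=gene
    )


def length_filter(
    reads: Iterable[TaggedRead],
    min_lengths: Mapping[str, int] = DEFAULT_MIN_LENGTH,
) -> List[TaggedRead]:
    """Keep reads meeting their gene's minimum length (boundary inclusive)."""
    kept = []
    for read in reads:
        if read.gene is None:
            continue
        if len(read.bases) >= min_lengths[read.gene]:
            kept.append(read)
    return kept


@dataclass
class ReadAccounting:
    """Counts along the filter cascade, with arithmetic identities enforced.

    ``post_chimera`` is derived (pre_chimera - chimera_flagged) and the
    constructor rejects negative or non-monotone counts.
    """

    raw: int
    demultiplexed: Optional[int] = None
    length_passed: Dict[str, int] = field(default_factory=dict)
    pre_chimera: Optional[int] = None
    chimera_flagged: int = 0
    singletons_removed: int = 0

    def __post_init__(self):
        counts = [self.raw, self.chimera_flagged, self.singletons_removed]
        counts += [c for c in (self.demultiplexed, self.pre_chimera) if c is not None]
        counts += list(self.length_passed.values())
        if any(int(c) != c or c < 0 for c in counts):
            raise AccountingError("read counts must be non-negative integers")
        if self.demultiplexed is not None and self.demultiplexed > self.raw:
            raise AccountingError("demultiplexed count exceeds raw count")
        if self.total_passed > self.raw:
            raise AccountingError("length-passed reads exceed raw count")
        if self.pre_chimera is None and self.length_passed:
            # by default chimera screening applies to the ITS fraction
            self.pre_chimera = self.length_passed.get("ITS", self.total_passed)
        if self.pre_chimera is not None and self.chimera_flagged > self.pre_chimera:
            raise AccountingError("more chimeras flagged than reads screened")

    @property
    def total_passed(self) -> int:
        return int(sum(self.length_passed.values()))

    @property
    def post_chimera(self) -> Optional[int]:
        if self.pre_chimera is None:
            return None
        return self.pre_chimera - self.chimera_flagged

    def to_dict(self) -> Dict[str, object]:
        return {
            "raw": self.raw,
            "demultiplexed": self.demultiplexed,
            "length_passed": dict(self.length_passed),
            "total_passed": self.total_passed,
            "pre_chimera": self.pre_chimera,
            "chimera_flagged": self.chimera_flagged,
            "post_chimera": self.post_chimera,
            "singletons_removed": self.singletons_removed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        genes = d.pop("length_passed")
        rows = [(k, v) for k, v in d.items()]
        rows += [(f"length_passed_{g}", n) for g, n in genes.items()]
        return pd.DataFrame(rows, columns=["stage", "reads"])


def account(
    raw: int,
    length_passed: Optional[Mapping[str, int]] = None,
    demultiplexed: Optional[int] = None,
    pre_chimera: Optional[int] = None,
    chimera_flagged: int = 0,
    singletons_removed: int = 0,
) -> ReadAccounting:
    """Build a validated :class:`ReadAccounting` report."""
    return ReadAccounting(
        raw=raw,
        demultiplexed=demultiplexed,
        length_passed=dict(length_passed or {}),
        pre_chimera=pre_chimera,
        chimera_flagged=chimera_flagged,
        singletons_removed=singletons_removed,
    )
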