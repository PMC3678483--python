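"""Presence/absence and plant x fungus matrices, richness summaries, curves.

The presence rule drops, per sample, OTUs representing less than 5% of the
sample's total reads; the total is taken after removal of nonfungal (host
plant / Metazoa) OTUs, since the per-sample read totals reported for the
final matrix follow that removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .otus import HostAssignment, OTUTable
from .taxonomy import LineageAssignment

PRESENCE_FRACTION = 0.05
NONFUNGAL_KINGDOMS = frozenset({"Viridiplantae", "Metazoa"})


@dataclass
class PresenceMatrix:
    """Binary sample x OTU occurrences plus per-sample habitat and read total."""

    presence: pd.DataFrame  # bool, index: sample ids, columns: otu ids
    habitat: pd.Series  # "root" / "soil" per sample
    retained_reads: pd.Series  # per-sample total after nonfungal removal

    @property
    def sample_ids(self) -> List[str]:
        return list(self.presence.index)

    @property
    def otu_ids(self) -> List[str]:
        return list(self.presence.columns)

    def subset(self, habitat: str) -> pd.DataFrame:
        return self.presence.loc[self.habitat == habitat]

    def to_tsv(self, path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t", index_label="sample_id")


def apply_presence_rules(
    table: OTUTable,
    assignments: Mapping[str, LineageAssignment],
    habitat: Mapping[str, str],
    min_fraction: float = PRESENCE_FRACTION,
) -> Tuple[PresenceMatrix, List[str]]:
    """Build the presence/absence matrix under the 5%-of-sample-reads rule.

    OTUs whose merged taxonomy places them in a nonfungal kingdom (host
    plants / Metazoa) are removed before per-sample totals are computed.
    Returns the matrix and the list of removed nonfungal OTU ids.
    """
    removed = [
        otu
        for otu in table.otu_ids
        if otu in assignments and assignments[otu].lineage[0] in NONFUNGAL_KINGDOMS
    ]
    counts = table.counts.drop(index=removed).T  # samples x OTUs
    totals = counts.sum(axis=1)
    thresh = (min_fraction * totals).to_numpy()[:, None]
    presence = pd.DataFrame(
        counts.to_numpy() >= np.maximum(thresh, 1),
        index=counts.index,
        columns=counts.columns,
    )
    hab = pd.Series({s: habitat[s] for s in counts.index}, name="habitat")
    return (
        PresenceMatrix(presence=presence, habitat=hab, retained_reads=totals),
        removed,
    )


@dataclass
class PlantFungusMatrix:
    """Plant species x fungal OTU counts of root samples showing the link."""

    counts: pd.DataFrame  # index: plant species, columns: otu ids
    samples_per_plant: pd.Series
    excluded_samples: List[str]

    def nonzero_links(self) -> int:
        return int((self.counts.to_numpy() > 0).sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="plant_species")


def build_plant_fungus_matrix(
    presence: PresenceMatrix,
    hosts: Iterable[HostAssignment],
) -> PlantFungusMatrix:
    """Count, per (plant, OTU), the root samples exhibiting the association.

    Root samples without a host assignment are excluded (and reported);
    soil samples never enter the web.
    """
    host_of = {h.sample_id: h.species for h in hosts if h is not None}
    root_samples = [s for s in presence.sample_ids if presence.habitat[s] == "root"]
    with_host = [s for s in root_samples if s in host_of]
    excluded = [s for s in root_samples if s not in host_of]
    plants = sorted({host_of[s] for s in with_host})
    mat = pd.DataFrame(0, index=plants, columns=presence.otu_ids, dtype=np.int64)
    per_plant = pd.Series(0, index=plants, dtype=np.int64)
    for s in with_host:
        plant = host_of[s]
        mat.loc[plant] += presence.presence.loc[s].to_numpy().astype(np.int64)
        per_plant[plant] += 1
    return PlantFungusMatrix(counts=mat, samples_per_plant=per_plant,
                             excluded_samples=excluded)


@dataclass
class RarefactionResult:
    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    axis: str


def accumulation_curve(
    data,
    axis: str = "samples",
    n_shuffles: int = 100,
    seed: int = 0,
) -> RarefactionResult:
    """OTU accumulation under random ordering, mean and SD over shuffles.

    ``axis='samples'``: ``data`` is a boolean/count sample x OTU frame; the
    curve is cumulative distinct OTUs against number of samples, over
    ``n_shuffles`` random sample-ID orders.

    ``axis='reads'``: ``data`` is a single sample's OTU count vector; reads
    are shuffled individually (classic individual-based rarefaction).
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2")
    rng = np.random.default_rng(seed)
    if axis == "samples":
        mat = (np.asarray(data, dtype=float) > 0)
        n = mat.shape[0]
        curves = np.empty((n_shuffles, n))
        for s in range(n_shuffles):
            order = rng.permutation(n)
            seen = np.cumsum(mat[order], axis=0) > 0
            curves[s] = seen.sum(axis=1)
        x = np.arange(1, n + 1)
    elif axis == "reads":
        counts = np.asarray(data, dtype=int)
        labels = np.repeat(np.arange(counts.size), counts)
        n = labels.size
        curves = np.empty((n_shuffles, n))
        for s in range(n_shuffles):
            order = rng.permutation(n)
            lab = labels[order]
            first = np.zeros(n, dtype=bool)
            _, first_idx = np.unique(lab, return_index=True)
            first[first_idx] = True
            curves[s] = np.cumsum(first)
        x = np.arange(1, n + 1)
    else:
        raise ValueError("axis must be 'samples' or 'reads'")
    return RarefactionResult(
        x=x, mean=curves.mean(axis=0), sd=curves.std(axis=0, ddof=1), axis=axis
    )


@dataclass
class CompositionSummary:
    """Identified fractions per rank plus per-taxon OTU tallies."""

    n_otus: int
    identified: Dict[str, int]  # rank -> OTUs assigned at that rank or deeper
    percentages: Dict[str, float]
    taxon_counts: Dict[str, Dict[str, int]]  # rank -> taxon -> OTU count


def composition_summary(
    assignments: Iterable[LineageAssignment],
    ranks: Sequence[str] = ("phylum", "order", "genus"),
) -> CompositionSummary:
    """Count and percentage of OTUs identified at each rank (or deeper)."""
    from .taxonomy import _RANK_INDEX  # local import to avoid cycle at module load

    assignments = list(assignments)
    n = len(assignments)
    identified: Dict[str, int] = {}
    percentages: Dict[str, float] = {}
    taxon_counts: Dict[str, Dict[str, int]] = {}
    for rank in ranks:
        ri = _RANK_INDEX[rank]
        names = [a.lineage[ri] for a in assignments if a.lineage[ri]]
        identified[rank] = len(names)
        percentages[rank] = 100.0 * len(names) / n if n else 0.0
        tally: Dict[str, int] = {}
        for name in names:
            tally[name] = tally.get(name, 0) + 1
        taxon_counts[rank] = tally
    return CompositionSummary(
        n_otus=n, identified=identified, percentages=percentages,
        taxon_counts=taxon_counts,
    )
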