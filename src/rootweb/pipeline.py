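"""End-to-end orchestration: tagged reads -> OTU table, taxonomy, matrices.

This is the thin glue over the per-stage modules; each stage can also be run
on its own.  Stage order and thresholds follow the survey protocol: QV-20
trimming, exact-MID demultiplexing, primer-based gene recognition, length
filters (400 bp rbcL / 150 bp ITS), within-sample clustering at 97%, chimera
flagging at score 0.1, among-sample clustering (97% ITS / 99.8% rbcL),
singleton and <5-read OTU removal, and the 100-read sample floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import otus as otumod
from . import reads as readmod
from .community import PresenceMatrix, apply_presence_rules, build_plant_fungus_matrix
from .otus import (
    HostAssignment,
    OTUTable,
    SeqCluster,
    assign_host,
    cluster_among_samples,
    cluster_within_sample,
    filter_otu_table,
    flag_chimeras,
)
from .reads import (
    PrimerSet,
    ReadAccounting,
    TaggedRead,
    classify_gene,
    demultiplex,
    length_filter,
    trim_quality_tail,
)
from .taxonomy import (
    EcotypeTable,
    LineageAssignment,
    ReferenceRecord,
    assign_ecotype,
    build_tier_db,
    find_homologs,
    merge_with_priority,
    relaxed_lca,
    strict_lca,
)


@dataclass
class PipelineResult:
    accounting: ReadAccounting
    otu_table: OTUTable
    raw_otu_table: OTUTable
    filter_report: otumod.FilterReport
    chimera_reads_flagged: int
    flagged_read_ids: List[str]
    host_assignments: List[HostAssignment]
    assignments: Dict[str, LineageAssignment]
    presence: Optional[PresenceMatrix] = None
    plant_fungus: Optional[object] = None
    nonfungal_otus: List[str] = field(default_factory=list)


def process_reads(
    raw_reads: Sequence[TaggedRead],
    mid_table: pd.DataFrame,
    primer_set: PrimerSet,
    min_qv: int = 20,
) -> Tuple[Dict[Tuple[str, str], List[TaggedRead]], Dict[str, int]]:
    """Trim, demultiplex, classify and length-filter; group by (sample, gene)."""
    trimmed = [trim_quality_tail(r, min_qv) for r in raw_reads]
    assigned, _rejected = demultiplex(trimmed, mid_table)
    classified = []
    for r in assigned:
        out = classify_gene(r, primer_set)
        if out is not None:
            classified.append(out)
    kept = length_filter(classified)
    groups: Dict[Tuple[str, str], List[TaggedRead]] = {}
    for r in kept:
        groups.setdefault((r.sample_id, r.gene), []).append(r)
    stage_counts = {
        "raw": len(raw_reads),
        "demultiplexed": len(assigned),
        "classified": len(classified),
        "length_passed_ITS": sum(1 for r in kept if r.gene == "ITS"),
        "length_passed_rbcL": sum(1 for r in kept if r.gene == "rbcL"),
    }
    return groups, stage_counts


def run_pipeline(
    raw_reads: Sequence[TaggedRead],
    mid_table: pd.DataFrame,
    primer_set: PrimerSet,
    plant_references: Optional[Sequence[Tuple[str, str, str]]] = None,
    reference_records: Optional[Sequence[ReferenceRecord]] = None,
    ecotype_table: Optional[EcotypeTable] = None,
    min_qv: int = 20,
    its_identity: float = otumod.ITS_IDENTITY,
    rbcl_identity: float = otumod.RBCL_IDENTITY,
    chimera_min_score: float = 0.1,
    build_matrices: bool = True,
) -> PipelineResult:
    """Run the full analysis on raw tagged reads.

    ``plant_references`` items are (id, species, sequence) rbcL references for
    host identification; ``reference_records`` feed the two-tier taxonomy.
    Either may be omitted to skip that stage.
    """
    groups, stage_counts = process_reads(raw_reads, mid_table, primer_set, min_qv)
    habitat = dict(zip(mid_table["sample_id"], mid_table["habitat"]))

    # --- fungal ITS: within-sample clustering + chimera flagging ------------
    its_consensi: List[Tuple[str, str, int]] = []
    flagged_read_ids: List[str] = []
    chimera_reads = 0
    for (sample, gene), reads_ in sorted(groups.items()):
        if gene != "ITS":
            continue
        clusters = cluster_within_sample(reads_, its_identity, sample_id=sample)
        flags = flag_chimeras(clusters, min_score=chimera_min_score)
        flagged = {f.cluster_index for f in flags}
        for i, cl in enumerate(clusters):
            if i in flagged:
                chimera_reads += cl.size
                flagged_read_ids.extend(cl.members)
            else:
                its_consensi.append((cl.consensus, sample, cl.size))
    raw_table, _ = cluster_among_samples(its_consensi, its_identity)
    otu_table, filter_report = filter_otu_table(raw_table)

    # --- host rbcL: per-sample consensus, among-sample clusters, matching ---
    host_assignments: List[HostAssignment] = []
    if plant_references:
        rbcl_consensi: List[Tuple[str, str, int]] = []
        for (sample, gene), reads_ in sorted(groups.items()):
            if gene != "rbcL" or not reads_:
                continue
            clusters = cluster_within_sample(reads_, its_identity, sample_id=sample)
            top = clusters[0]  # dominant cluster = the root's own plant
            rbcl_consensi.append((top.consensus, sample, top.size))
        _, rbcl_clusters = cluster_among_samples(
            rbcl_consensi, rbcl_identity, otu_prefix="RBCL"
        )
        for cl in rbcl_clusters:
            hit = assign_host(cl.consensus, plant_references)
            if hit is None:
                continue
            for member in cl.members:
                sample = member.rsplit(":", 1)[0]
                host_assignments.append(
                    HostAssignment(sample_id=sample, species=hit.species,
                                   identity=hit.identity,
                                   reference_id=hit.reference_id)
                )

    # --- taxonomy ------------------------------------------------------------
    assignments: Dict[str, LineageAssignment] = {}
    if reference_records:
        genus_db = build_tier_db(reference_records, "genus")
        class_db = build_tier_db(reference_records, "class")
        eco_table = ecotype_table or EcotypeTable.default()
        for otu_id in otu_table.otu_ids:
            seq = otu_table.consensus[otu_id]
            hits_g = find_homologs(seq, genus_db, query_id=otu_id)
            hits_c = find_homologs(seq, class_db, query_id=otu_id)
            merged = merge_with_priority(
                strict_lca(hits_g, genus_db),
                strict_lca(hits_c, class_db),
                relaxed_lca(hits_g, genus_db),
                otu_id=otu_id,
            )
            merged.ecotype = assign_ecotype(merged, eco_table)
            assignments[otu_id] = merged

    # --- matrices ------------------------------------------------------------
    presence = None
    plant_fungus = None
    nonfungal: List[str] = []
    if build_matrices:
        presence, nonfungal = apply_presence_rules(otu_table, assignments, habitat)
        if host_assignments:
            plant_fungus = build_plant_fungus_matrix(presence, host_assignments)

    accounting = readmod.account(
        raw=stage_counts["raw"],
        demultiplexed=stage_counts["demultiplexed"],
        length_passed={
            "ITS": stage_counts["length_passed_ITS"],
            "rbcL": stage_counts["length_passed_rbcL"],
        },
        chimera_flagged=chimera_reads,
        singletons_removed=filter_report.singleton_reads,
    )
    return PipelineResult(
        accounting=accounting,
        otu_table=otu_table,
        raw_otu_table=raw_table,
        filter_report=filter_report,
        chimera_reads_flagged=chimera_reads,
        flagged_read_ids=flagged_read_ids,
        host_assignments=host_assignments,
        assignments=assignments,
        presence=presence,
        plant_fungus=plant_fungus,
        nonfungal_otus=nonfungal,
    )
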