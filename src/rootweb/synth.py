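"""Ground-truthed synthetic communities, reference databases and tagged reads.

The generator emulates a tag-encoded amplicon survey of the root-associated
fungal community of a temperate forest plot: a dozen plant species with one
dominant host, a few dozen fungal OTUs spanning ectomycorrhizal, arbuscular,
root-endophytic and "other" ecotypes, root and soil samples, and 454-style
single-end reads (8-mer molecular ID + degenerate forward primer + template)
with decaying 3' quality, substitution errors and two-parent chimeras.

Design of the stochastic model:

* Host preference: each fungus draws a host-use profile from a Dirichlet
  whose mean is the plant abundance vector and whose concentration is the
  per-fungus ``host_concentration`` knob -- small values give one-host
  specialists (high d'), large values give availability-tracking generalists
  (d' near 0).
* Habitat: per-fungus ``root_affinity`` splits each fungus's weight between
  the root and soil pools; root-sample compositions additionally condition on
  the sample's host plant.
* Per-sample composition: Dirichlet around the conditional fungal weights
  with a modest concentration, so a root fragment is dominated by a handful
  of OTUs, as real terminal-root samples are.
* Sequences: i.i.d. uniform nucleotides (mutually ~50% identical, far below
  every clustering threshold) -- identity thresholds behave as designed
  without real ITS secondary structure.
* Errors: per-base substitutions only; 3' quality decays linearly from a
  plateau of QV 38 to ~QV 10 over the final quarter of the read, with jitter,
  so the QV-20 trimmer has work to do without destroying reads.
* MIDs: pairwise Hamming distance >= 3, so a single substitution can never
  silently reassign a read to another sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reads import MID_LENGTH, IUPAC, PrimerSet, TaggedRead
from .taxonomy import RANKS, ReferenceRecord

ECOTYPE_KEYS = ("ectomycorrhizal", "arbuscular", "endophyte", "other")

# Standard-style degenerate forward primers (a handful of IUPAC positions so
# the primer matcher is exercised).
DEFAULT_PRIMERS = PrimerSet(
    primers={
        "ITS": "GCATCRATGAAGAWCGCAGC",
        "rbcL": "CCAMAAACRGARACTAAAGC",
    },
    tolerance=2,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class QualityModel:
    """Plateau-and-decay per-base quality profile (QV scale)."""

    plateau: float = 38.0
    floor: float = 10.0
    tail_fraction: float = 0.25
    jitter_sd: float = 2.0

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        pos = np.arange(length)
        start = int(np.floor((1.0 - self.tail_fraction) * length))
        q = np.full(length, self.plateau, dtype=float)
        tail = length - start
        if tail > 0:
            q[start:] = self.plateau + (self.floor - self.plateau) * (
                (pos[start:] - start + 1) / tail
            )
        q += rng.normal(0.0, self.jitter_sd, size=length)
        return np.clip(np.round(q), 2, 41).astype(np.int16)


def _default_plant_weights(n_plants: int, dominant: float = 0.45) -> np.ndarray:
    """One dominant host; the rest decay geometrically."""
    if n_plants == 1:
        return np.ones(1)
    rest = 0.8 ** np.arange(n_plants - 1)
    rest = rest / rest.sum() * (1.0 - dominant)
    return np.concatenate(([dominant], rest))


_DEFAULT_ECOTYPE_COUNTS = {
    "ectomycorrhizal": 14, "arbuscular": 3, "endophyte": 8, "other": 15,
}
# Per-ecotype defaults for the two preference knobs: ectomycorrhizal fungi are
# host specialists found in both habitats; endophytes are host generalists
# nearly restricted to roots.
_DEFAULT_CONCENTRATION = {
    "ectomycorrhizal": 0.15, "arbuscular": 20.0, "endophyte": 50.0, "other": 5.0,
}
_DEFAULT_ROOT_AFFINITY = {
    "ectomycorrhizal": 0.65, "arbuscular": 0.60, "endophyte": 0.97, "other": 0.50,
}


@dataclass
class CommunitySpec:
    """Parameters of the synthetic world.  Defaults mirror the survey design:
    ~12 plant species with one dominant, ~40 fungal OTUs of four ecotypes,
    150 root + 40 soil samples, 106-635 reads per sample, 0.5% substitution
    errors and 2% chimeras."""

    n_plants: int = 12
    plant_abundance_weights: Optional[Sequence[float]] = None
    n_fungi_per_ecotype: Dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_ECOTYPE_COUNTS)
    )
    host_concentration: Optional[Sequence[float]] = None  # per fungus
    root_affinity: Optional[Sequence[float]] = None  # per fungus
    n_root_samples: int = 150
    n_soil_samples: int = 40
    depth_range: Tuple[int, int] = (106, 635)
    rbcl_depth: int = 20
    error_rate: float = 0.005
    chimera_rate: float = 0.02
    quality_decay: QualityModel = field(default_factory=QualityModel)
    mid_length: int = MID_LENGTH
    seed: int = 0
    its_length: int = 220
    # long enough that the ~18% expected 3' trim leaves > 400 bp of template
    rbcl_length: int = 560
    sample_concentration: float = 8.0

    def __post_init__(self):
        if self.plant_abundance_weights is None:
            self.plant_abundance_weights = _default_plant_weights(self.n_plants)
        self.plant_abundance_weights = np.asarray(
            self.plant_abundance_weights, dtype=float
        )
        if abs(self.plant_abundance_weights.sum() - 1.0) > 1e-9:
            raise ValueError("plant abundance weights must sum to 1")
        if len(self.plant_abundance_weights) != self.n_plants:
            raise ValueError("need one abundance weight per plant")
        for rate in (self.error_rate, self.chimera_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be a valid interval with minimum >= 1")
        unknown = set(self.n_fungi_per_ecotype) - set(ECOTYPE_KEYS)
        if unknown:
            raise ValueError(f"unknown ecotypes: {sorted(unknown)}")
        n = self.n_fungi
        eco = self.ecotype_of_fungus()
        if self.host_concentration is None:
            self.host_concentration = np.array(
                [_DEFAULT_CONCENTRATION[e] for e in eco]
            )
        self.host_concentration = np.asarray(self.host_concentration, dtype=float)
        if self.root_affinity is None:
            self.root_affinity = np.array([_DEFAULT_ROOT_AFFINITY[e] for e in eco])
        self.root_affinity = np.asarray(self.root_affinity, dtype=float)
        if len(self.host_concentration) != n or len(self.root_affinity) != n:
            raise ValueError("per-fungus parameter vectors must match fungus count")
        if (self.host_concentration < 0).any():
            raise ValueError("host_concentration must be non-negative")
        if ((self.root_affinity < 0) | (self.root_affinity > 1)).any():
            raise ValueError("root_affinity must lie in [0, 1]")

    @property
    def n_fungi(self) -> int:
        return sum(self.n_fungi_per_ecotype.get(k, 0) for k in ECOTYPE_KEYS)

    def ecotype_of_fungus(self) -> List[str]:
        out: List[str] = []
        for key in ECOTYPE_KEYS:
            out.extend([key] * self.n_fungi_per_ecotype.get(key, 0))
        return out

    def to_json_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["plant_abundance_weights"] = list(map(float, self.plant_abundance_weights))
        d["host_concentration"] = list(map(float, self.host_concentration))
        d["root_affinity"] = list(map(float, self.root_affinity))
        return d


@dataclass
class GroundTruth:
    """Everything the generator knows: the answer key for the pipeline."""

    spec: CommunitySpec
    fungal_sequences: Dict[str, str]
    lineages: Dict[str, Tuple[str, ...]]
    ecotypes: Dict[str, str]
    plant_sequences: Dict[str, str]
    plant_weights: pd.Series
    host_profiles: pd.DataFrame  # fungus x plant host-use probabilities
    sample_compositions: pd.DataFrame  # sample x fungus true proportions
    sample_hosts: Dict[str, Optional[str]]
    mid_table: pd.DataFrame  # sample_id, mid, habitat

    def to_json(self, path) -> None:
        payload = {
            "spec": self.spec.to_json_dict(),
            "fungal_sequences": self.fungal_sequences,
            "lineages": {k: list(v) for k, v in self.lineages.items()},
            "ecotypes": self.ecotypes,
            "plant_sequences": self.plant_sequences,
            "plant_weights": self.plant_weights.to_dict(),
            "sample_hosts": self.sample_hosts,
            "mid_table": self.mid_table.to_dict(orient="records"),
            "sample_compositions": {
                s: self.sample_compositions.loc[s].to_dict()
                for s in self.sample_compositions.index
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, rng: np.random.Generator, n_mut: int) -> str:
    """Apply exactly n_mut substitutions at distinct positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def _generate_mids(
    n: int, rng: np.random.Generator, length: int = MID_LENGTH, min_dist: int = 3,
    max_attempts: int = 500_000,
) -> List[str]:
    mids: List[str] = []
    arrs: List[np.ndarray] = []
    attempts = 0
    while len(mids) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not build a MID set at the required distance")
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_dist for a in arrs):
            arrs.append(cand)
            mids.append("".join("ACGT"[b] for b in cand))
    return mids


def _fungus_ids(spec: CommunitySpec) -> List[str]:
    return [f"F{i + 1:03d}" for i in range(spec.n_fungi)]


_ECOTYPE_TAXONOMY = {
    # ecotype -> (phylum, class, order)
    "ectomycorrhizal": ("Basidiomycota", "Agaricomycetes", "Russulales"),
    "arbuscular": ("Glomeromycota", "Glomeromycetes", "Glomerales"),
    "endophyte": ("Ascomycota", "Leotiomycetes", "Helotiales"),
    "other": ("Ascomycota", "Sordariomycetes", "Hypocreales"),
}


def generate_community(spec: CommunitySpec) -> GroundTruth:
    """Draw the true community: sequences, taxonomy, preferences, samples.

    Deterministic under ``spec.seed``.  ``host_concentration`` of 0 gives a
    one-host specialist (degenerate Dirichlet); ``numpy.inf`` gives a host
    profile exactly proportional to plant abundance (generalist limit).
    """
    rng = np.random.default_rng(spec.seed)
    plants = [f"Plant_{i + 1:02d}" for i in range(spec.n_plants)]
    w = spec.plant_abundance_weights
    plant_weights = pd.Series(w, index=plants)

    # Host rbcL references: a common backbone with ~2% per-species divergence,
    # comfortably apart at the 99.8% clustering threshold.
    backbone = _random_seq(rng, spec.rbcl_length)
    n_div = max(4, int(round(0.02 * spec.rbcl_length)))
    plant_sequences = {p: _mutate(backbone, rng, n_div) for p in plants}

    fungi = _fungus_ids(spec)
    eco_of = dict(zip(fungi, spec.ecotype_of_fungus()))
    fungal_sequences = {f: _random_seq(rng, spec.its_length) for f in fungi}

    lineages: Dict[str, Tuple[str, ...]] = {}
    fam_counter: Dict[str, int] = {}
    for i, f in enumerate(fungi):
        eco = eco_of[f]
        phylum, cls, order = _ECOTYPE_TAXONOMY[eco]
        fam_idx = fam_counter.setdefault(eco, 0)
        # two genera per family
        family = f"Fam_{eco[:3]}_{fam_idx // 2 + 1:02d}"
        fam_counter[eco] += 1
        genus = f"Genus_{f}"
        species = f"{genus}_sp"
        lineages[f] = ("Fungi", phylum, cls, order, family, genus, species)

    # Host-use profiles.
    n_fungi = spec.n_fungi
    profiles = np.empty((n_fungi, spec.n_plants))
    for i, f in enumerate(fungi):
        c = spec.host_concentration[i]
        if np.isinf(c):
            profiles[i] = w
        elif c == 0:
            host = rng.choice(spec.n_plants, p=w)
            profiles[i] = 0.0
            profiles[i, host] = 1.0
        else:
            profiles[i] = rng.dirichlet(c * spec.n_plants * w)
    host_profiles = pd.DataFrame(profiles, index=fungi, columns=plants)

    # Base (community-wide) fungal abundances: lognormal rank-abundance.
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_fungi)
    base /= base.sum()

    samples = [f"R{i + 1:03d}" for i in range(spec.n_root_samples)]
    samples += [f"S{i + 1:03d}" for i in range(spec.n_soil_samples)]
    habitats = ["root"] * spec.n_root_samples + ["soil"] * spec.n_soil_samples
    mids = _generate_mids(len(samples), rng, spec.mid_length)
    mid_table = pd.DataFrame(
        {"sample_id": samples, "mid": mids, "habitat": habitats}
    )

    comps = np.zeros((len(samples), n_fungi))
    sample_hosts: Dict[str, Optional[str]] = {}
    root_aff = spec.root_affinity
    for si, (s, hab) in enumerate(zip(samples, habitats)):
        if hab == "root":
            host_idx = int(rng.choice(spec.n_plants, p=w))
            sample_hosts[s] = plants[host_idx]
            weight = base * profiles[:, host_idx] * root_aff
        else:
            sample_hosts[s] = None
            weight = base * (1.0 - root_aff)
        if weight.sum() <= 0:
            raise ValueError(
                "a requested habitat has zero total fungal weight; check "
                "root_affinity and ecotype counts"
            )
        weight = weight / weight.sum()
        alpha = spec.sample_concentration * np.maximum(weight, 1e-12) * n_fungi
        comps[si] = rng.dirichlet(alpha)
    sample_compositions = pd.DataFrame(comps, index=samples, columns=fungi)

    return GroundTruth(
        spec=spec,
        fungal_sequences=fungal_sequences,
        lineages=lineages,
        ecotypes=eco_of,
        plant_sequences=plant_sequences,
        plant_weights=plant_weights,
        host_profiles=host_profiles,
        sample_compositions=sample_compositions,
        sample_hosts=sample_hosts,
        mid_table=mid_table,
    )


# ---------------------------------------------------------------------------
# Reference databases
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCollection:
    """Reference records plus the ground-truth annotation bookkeeping."""

    records: List[ReferenceRecord]
    truth_table: pd.DataFrame  # record_id, otu, annotation_rank, genus_wrong

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")

    def lineage_frame(self) -> pd.DataFrame:
        rows = [(r.id, *r.lineage) for r in self.records]
        return pd.DataFrame(rows, columns=["id", *RANKS])

    def to_lineage_tsv(self, path) -> None:
        df = self.lineage_frame()
        df["annotation_rank"] = self.truth_table.set_index("record_id").loc[
            df["id"], "annotation_rank"
        ].to_numpy()
        df.to_csv(path, sep="\t", index=False)


def generate_reference_taxonomy(
    truth: GroundTruth,
    misannotation_rate: float = 0.0,
    n_refs_per_otu: int = 25,
    genus_fraction: float = 0.8,
    class_fraction: float = 0.16,
    seed: Optional[int] = None,
) -> ReferenceCollection:
    """Emit reference records of varying annotation depth around each OTU.

    Each OTU receives ``n_refs_per_otu`` database relatives (1-3 substitutions
    away, i.e. ~99% identical) whose lineages are truncated at genus/species,
    class, or phylum level in the given proportions.  Exactly
    ``round(misannotation_rate * n_genus_records)`` genus-level records carry
    the full lineage of a *different* genus, spread across OTUs as evenly as
    the total allows (largest-remainder allocation), and are flagged in the
    ground-truth table.
    """
    if not (0.0 <= misannotation_rate <= 0.5):
        raise ValueError(
            "misannotation_rate above 0.5 breaks the majority-true assumption"
        )
    rng = np.random.default_rng(truth.spec.seed + 10_007 if seed is None else seed)
    fungi = list(truth.fungal_sequences)
    n_genus = int(round(genus_fraction * n_refs_per_otu))
    n_class = int(round(class_fraction * n_refs_per_otu))
    n_shallow = n_refs_per_otu - n_genus - n_class

    records: List[ReferenceRecord] = []
    rows = []
    # Largest-remainder allocation of the global misannotation quota.
    total_genus = n_genus * len(fungi)
    total_wrong = int(round(misannotation_rate * total_genus))
    share = total_wrong / len(fungi) if fungi else 0.0
    base_wrong = int(share)
    remainder = total_wrong - base_wrong * len(fungi)
    order = rng.permutation(len(fungi))
    wrong_quota = {f: base_wrong for f in fungi}
    for idx in order[:remainder]:
        wrong_quota[fungi[idx]] += 1

    for f in fungi:
        true_lin = truth.lineages[f]
        seq = truth.fungal_sequences[f]
        others = [g for g in fungi if g != f]
        wrong_ids = set(range(wrong_quota[f]))  # first k genus refs are wrong
        for j in range(n_refs_per_otu):
            rid = f"REF_{f}_{j + 1:03d}"
            rseq = _mutate(seq, rng, int(rng.integers(1, 4)))
            if j < n_genus:
                if j in wrong_ids:
                    donor = others[int(rng.integers(0, len(others)))]
                    lin = truth.lineages[donor]
                    rank = "genus"
                    wrong = True
                else:
                    lin = true_lin
                    rank = "genus"
                    wrong = False
            elif j < n_genus + n_class:
                lin = true_lin[:3] + ("",) * 4  # kingdom..class only
                rank = "class"
                wrong = False
            else:
                lin = true_lin[:2] + ("",) * 5  # kingdom, phylum
                rank = "phylum"
                wrong = False
            records.append(ReferenceRecord(id=rid, sequence=rseq, lineage=lin))
            rows.append((rid, f, rank, wrong))
    truth_table = pd.DataFrame(
        rows, columns=["record_id", "otu", "annotation_rank", "genus_wrong"]
    )
    return ReferenceCollection(records=records, truth_table=truth_table)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimulation:
    """Simulated reads plus the per-read provenance the tests audit."""

    reads: List[TaggedRead]
    provenance: pd.DataFrame
    primer_set: PrimerSet

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                qual = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracies the way a synthesized primer pool would."""
    out = []
    for ch in primer:
        opts = IUPAC[ch]
        out.append(opts[int(rng.integers(0, len(opts)))] if len(opts) > 1 else opts)
    return "".join(out)


def simulate_reads(truth: GroundTruth, spec: Optional[CommunitySpec] = None) -> ReadSimulation:
    """Generate the tag-encoded FASTQ-style read set for a community.

    Each read is MID + forward primer (degeneracies resolved per molecule) +
    template; substitution errors at ``error_rate`` apply to the whole read,
    and a ``chimera_rate`` fraction of fungal reads splice two same-sample
    parent templates at a crossover uniform in the middle 60% of the
    template.  Per-read provenance (sample, source, chimera parents, and
    error counts in the MID/primer regions) is recorded for auditing.
    Deterministic under the community seed.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed + 20_011)
    fungi = list(truth.fungal_sequences)
    f_seqs = truth.fungal_sequences
    its_primer = DEFAULT_PRIMERS.primers["ITS"]
    rbcl_primer = DEFAULT_PRIMERS.primers["rbcL"]
    mid_of = dict(zip(truth.mid_table["sample_id"], truth.mid_table["mid"]))
    qual_model = spec.quality_decay

    reads: List[TaggedRead] = []
    prov_rows = []

    def emit(sample: str, gene: str, template: str, source: str,
             is_chimera: bool, parents: Tuple[str, str], idx: int) -> None:
        primer = its_primer if gene == "ITS" else rbcl_primer
        primer_real = _realize_primer(primer, rng)
        mid = mid_of[sample]
        full = mid + primer_real + template
        arr = np.frombuffer(full.encode(), dtype=np.uint8).copy()
        err_pos = np.nonzero(rng.random(len(arr)) < spec.error_rate)[0]
        for p in err_pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = choices[int(rng.integers(0, 3))]
        bases = arr.tobytes().decode()
        mid_errors = int((err_pos < len(mid)).sum())
        plen = len(primer)
        primer_errors = int(
            ((err_pos >= len(mid)) & (err_pos < len(mid) + plen)).sum()
        )
        quals = qual_model.sample(len(bases), rng)
        rid = f"{sample}_{gene}_{idx:05d}"
        reads.append(TaggedRead(id=rid, bases=bases, qualities=quals))
        prov_rows.append(
            (rid, sample, gene, source, is_chimera, parents[0], parents[1],
             mid_errors, primer_errors)
        )

    for s in truth.sample_compositions.index:
        comp = truth.sample_compositions.loc[s].to_numpy()
        depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        n_chim = rng.binomial(depth, spec.chimera_rate)
        srcs = rng.choice(len(fungi), size=depth, p=comp)
        for i in range(depth):
            if i < n_chim and len(fungi) > 1:
                pa = int(srcs[i])
                pb = int(rng.choice(len(fungi), p=comp))
                while pb == pa:
                    pb = int(rng.choice(len(fungi), p=comp))
                ta, tb = f_seqs[fungi[pa]], f_seqs[fungi[pb]]
                lo = int(0.2 * len(ta))
                hi = int(0.8 * len(ta))
                k = int(rng.integers(lo, hi))
                template = ta[:k] + tb[k:]
                emit(s, "ITS", template, "chimera", True,
                     (fungi[pa], fungi[pb]), i)
            else:
                src = fungi[int(srcs[i])]
                emit(s, "ITS", f_seqs[src], src, False, ("", ""), i)
        host = truth.sample_hosts[s]
        if host is not None:
            for i in range(spec.rbcl_depth):
                emit(s, "rbcL", truth.plant_sequences[host], host,
                     False, ("", ""), i)

    provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "sample_id", "gene", "source", "is_chimera",
                 "parent_a", "parent_b", "mid_errors", "primer_errors"],
    )
    return ReadSimulation(reads=reads, provenance=provenance,
                          primer_set=DEFAULT_PRIMERS)


def expected_abundant_otus(
    sim: ReadSimulation, min_reads: int = 5, max_primer_errors: int = 2
) -> List[str]:
    """Planted OTUs expected to survive the >=5-reads-in-a-sample rule.

    Counts, per (OTU, sample), the non-chimeric fungal reads that demultiplex
    cleanly (error-free MID) and carry a recognizable primer; OTUs reaching
    ``min_reads`` in at least one sample should be recovered by the pipeline.
    """
    df = sim.provenance
    ok = (
        (df["gene"] == "ITS")
        & (~df["is_chimera"])
        & (df["mid_errors"] == 0)
        & (df["primer_errors"] <= max_primer_errors)
    )
    counts = (
        df[ok].groupby(["source", "sample_id"]).size().groupby("source").max()
    )
    return sorted(counts.index[counts >= min_reads])
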