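"""Habitat- and host-preference statistics for the root-associated community.

* CLAM multinomial classification of each OTU as root specialist, soil
  specialist, generalist, or too rare, using exact one-sided binomial
  boundary tests at the "supermajority" specialization boundary (K = 2/3)
  with sample-size scaling.
* The d' specialization index (normalized Kullback-Leibler divergence of a
  node's partner use from partner availability) with integer-constrained
  extremes, and its significance against a vaznull permutation ensemble
  that preserves the grand total and the number of links.
* Ecotype co-occurrence summaries within root samples, and an edge-list
  export of the bipartite plant-fungus web.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .community import PlantFungusMatrix, PresenceMatrix
from .taxonomy import LineageAssignment


# ---------------------------------------------------------------------------
# CLAM habitat classification
# ---------------------------------------------------------------------------

@dataclass
class ClamConfig:
    """Supermajority boundary K, per-species alpha, and habitat sample sizes.

    The boundary test for (say) root specialists asks: if the OTU sat exactly
    on the K-supermajority boundary, corrected for unequal sampling of the two
    habitats, how unlikely is a soil occurrence count this small?  Under the
    boundary the probability that one occurrence falls in soil is

        p0 = (1 - K) * N_soil / (K * N_root + (1 - K) * N_soil).
    """

    n_root: int
    n_soil: int
    k: float = 2.0 / 3.0
    alpha: float = 0.05

    def __post_init__(self):
        if not (0.5 < self.k < 1.0):
            raise ValueError("K must be in (0.5, 1)")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if self.n_root <= 0 or self.n_soil <= 0:
            raise ValueError("both habitats need at least one sample")

    @property
    def p0_root(self) -> float:
        """P(single occurrence in soil | root-specialist boundary)."""
        return ((1 - self.k) * self.n_soil) / (
            self.k * self.n_root + (1 - self.k) * self.n_soil
        )

    @property
    def p0_soil(self) -> float:
        """P(single occurrence in root | soil-specialist boundary)."""
        return ((1 - self.k) * self.n_root) / (
            self.k * self.n_soil + (1 - self.k) * self.n_root
        )

    def min_total_root(self) -> int:
        """Smallest total count at which the root test could reach alpha."""
        return int(math.ceil(math.log(self.alpha) / math.log(1 - self.p0_root)))

    def min_total_soil(self) -> int:
        return int(math.ceil(math.log(self.alpha) / math.log(1 - self.p0_soil)))

    def min_classifiable_total(self) -> int:
        """Totals below this cannot be classified: some boundary test can
        never reach alpha, so a non-significant result is uninformative."""
        return max(self.min_total_root(), self.min_total_soil())


ROOT_SPECIALIST = "root_specialist"
SOIL_SPECIALIST = "soil_specialist"
GENERALIST = "generalist"
TOO_RARE = "too_rare"


def clam_pvalues(y_root: int, y_soil: int, cfg: ClamConfig) -> Tuple[float, float]:
    """One-sided exact binomial boundary p-values (root test, soil test)."""
    total = y_root + y_soil
    p_root = float(stats.binom.cdf(y_soil, total, cfg.p0_root))
    p_soil = float(stats.binom.cdf(y_root, total, cfg.p0_soil))
    return p_root, p_soil


def clam_classify(y_root: int, y_soil: int, cfg: ClamConfig) -> str:
    """Classify one OTU from its habitat occurrence counts."""
    if y_root < 0 or y_soil < 0:
        raise ValueError("occurrence counts must be non-negative")
    total = y_root + y_soil
    if total == 0:
        return TOO_RARE
    p_root, p_soil = clam_pvalues(y_root, y_soil, cfg)
    # Both one-sided tests significant is impossible for K > 1/2.
    if p_root < cfg.alpha:
        return ROOT_SPECIALIST
    if p_soil < cfg.alpha:
        return SOIL_SPECIALIST
    if total >= cfg.min_classifiable_total():
        return GENERALIST
    return TOO_RARE


@dataclass
class ClamResult:
    table: pd.DataFrame  # otu, y_root, y_soil, classification, p_root, p_soil
    counts: Dict[str, int]
    config: ClamConfig


def clam_classify_all(presence: PresenceMatrix, cfg: Optional[ClamConfig] = None) -> ClamResult:
    """Classify every OTU in a presence matrix with both habitats sampled."""
    habitats = set(presence.habitat)
    if not {"root", "soil"} <= habitats:
        raise ValueError("presence matrix must contain both root and soil samples")
    root = presence.subset("root")
    soil = presence.subset("soil")
    if cfg is None:
        cfg = ClamConfig(n_root=len(root), n_soil=len(soil))
    rows = []
    for otu in presence.otu_ids:
        yr = int(root[otu].sum())
        ys = int(soil[otu].sum())
        p_root, p_soil = clam_pvalues(yr, ys, cfg) if yr + ys else (1.0, 1.0)
        rows.append((otu, yr, ys, clam_classify(yr, ys, cfg), p_root, p_soil))
    table = pd.DataFrame(
        rows, columns=["otu", "y_root", "y_soil", "classification", "p_root", "p_soil"]
    ).set_index("otu")
    counts = table["classification"].value_counts().to_dict()
    return ClamResult(table=table, counts=counts, config=cfg)


# ---------------------------------------------------------------------------
# d' specialization index
# ---------------------------------------------------------------------------

@dataclass
class DPrimeResult:
    node: str
    d: float
    d_min: float
    d_max: float
    d_prime: float
    p_value: Optional[float] = None
    n_permutations: Optional[int] = None


def _kl_row(alloc: np.ndarray, q: np.ndarray) -> float:
    """d = sum_j p'_j ln(p'_j / q_j) over nonzero cells of one row."""
    total = alloc.sum()
    nz = alloc > 0
    p = alloc[nz] / total
    return float(np.sum(p * np.log(p / q[nz])))


def _d_min_greedy(total: int, q: np.ndarray) -> float:
    """Minimum d over integer allocations of ``total`` across partners.

    The objective is separable and convex in each cell, so incremental greedy
    allocation (always add the next unit where it increases d least) is
    exactly optimal.
    """
    n = q.size
    alloc = np.zeros(n, dtype=np.int64)

    def cell_term(a: float, qj: float) -> float:
        if a == 0:
            return 0.0
        p = a / total
        return p * math.log(p / qj)

    current = np.zeros(n)
    for _ in range(total):
        deltas = np.array(
            [cell_term(alloc[j] + 1, q[j]) - current[j] for j in range(n)]
        )
        j = int(np.argmin(deltas))
        alloc[j] += 1
        current[j] += deltas[j]
    return float(current.sum())


def dprime(
    matrix,
    node,
    axis: str = "rows",
) -> DPrimeResult:
    """d' of one node (row by default) of a plant x fungus count matrix.

    ``matrix`` may be a :class:`PlantFungusMatrix`, a DataFrame, or an array;
    ``node`` is a row label (column label with ``axis='columns'``) or integer
    index for arrays.  d is the Kullback-Leibler divergence of the node's
    partner distribution from partner availability; d_min / d_max are the
    extremes over integer reallocations of the node's total across partners
    (d_max is attained by concentrating everything on the rarest partner;
    d_min by exactly-optimal greedy allocation), and d' = (d - d_min) /
    (d_max - d_min), defined as 0 when the extremes coincide.
    """
    if isinstance(matrix, PlantFungusMatrix):
        df = matrix.counts
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix))
    if axis == "columns":
        df = df.T
    arr = df.to_numpy(dtype=np.int64)
    loc = list(df.index).index(node) if node in df.index else int(node)
    d, d_min, d_max, d_prime = _dprime_array(arr, loc)
    return DPrimeResult(node=str(node), d=d, d_min=d_min, d_max=d_max,
                        d_prime=d_prime)


def _dprime_array(arr: np.ndarray, row_idx: int) -> Tuple[float, float, float, float]:
    m = arr.sum()
    col_totals = arr.sum(axis=0)
    if (col_totals == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("matrix must have no empty rows or columns")
    q = col_totals / m
    row = arr[row_idx]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"row {row_idx} has no interactions")
    d = _kl_row(row, q)
    d_max = float(-np.log(q.min()))
    d_min = _d_min_greedy(total, q)
    if d_max - d_min > 1e-12:
        d_prime = (d - d_min) / (d_max - d_min)
    else:
        d_prime = 0.0
    return d, d_min, d_max, min(1.0, max(0.0, d_prime))


# ---------------------------------------------------------------------------
# vaznull null model
# ---------------------------------------------------------------------------

def vaznull_sample(matrix, rng) -> np.ndarray:
    """One vaznull randomization of a bipartite count matrix.

    Cells are selected without replacement with probability proportional to
    (row total x column total) until the observed link count is reached, under
    the constraint that every row and column ends up with at least one link;
    the remaining interaction events are then distributed multinomially over
    the selected cells with the same probabilities.  The grand total and the
    link count are preserved exactly.
    """
    if isinstance(matrix, PlantFungusMatrix):
        arr = matrix.counts.to_numpy(dtype=np.int64)
    else:
        arr = np.asarray(matrix, dtype=np.int64)
    nr, nc = arr.shape
    m = int(arr.sum())
    links = int((arr > 0).sum())
    if links < max(nr, nc):
        raise ValueError("link count cannot cover every row and column")
    r = arr.sum(axis=1).astype(float)
    c = arr.sum(axis=0).astype(float)
    probs = np.outer(r, c).ravel()
    probs = probs / probs.sum()

    selected = np.zeros(nr * nc, dtype=bool)
    row_cov = np.zeros(nr, dtype=bool)
    col_cov = np.zeros(nc, dtype=bool)
    n_sel = 0
    rows_idx = np.repeat(np.arange(nr), nc)
    cols_idx = np.tile(np.arange(nc), nr)
    while n_sel < links:
        remaining = links - n_sel
        # Invariant: remaining picks must still be able to cover every
        # uncovered row and column (one pick covers at most one of each), so
        # when the budget is tight only margin-covering cells are eligible.
        ur = int((~row_cov).sum())
        uc = int((~col_cov).sum())
        cand = ~selected
        if remaining <= ur:
            cand &= ~row_cov[rows_idx]
        if remaining <= uc:
            cand &= ~col_cov[cols_idx]
        w = probs * cand
        ws = w.sum()
        if ws <= 0:  # pragma: no cover - guarded by the precondition
            raise RuntimeError("vaznull selection ran out of feasible cells")
        cell = rng.choice(nr * nc, p=w / ws)
        selected[cell] = True
        row_cov[rows_idx[cell]] = True
        col_cov[cols_idx[cell]] = True
        n_sel += 1

    out = np.zeros(nr * nc, dtype=np.int64)
    out[selected] = 1
    rest = m - links
    if rest > 0:
        psel = probs[selected]
        extra = rng.multinomial(rest, psel / psel.sum())
        out[selected] += extra
    return out.reshape(nr, nc)


def dprime_significance(
    matrix,
    node,
    n_perm: int = 10_000,
    seed: int = 0,
    axis: str = "rows",
) -> DPrimeResult:
    """d' of a node with a one-sided vaznull permutation p-value.

    p = (1 + #{null d' >= observed d'}) / (1 + n_perm); the add-one estimator
    avoids p = 0.  Deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(matrix, PlantFungusMatrix):
        df = matrix.counts
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix))
    obs = dprime(df, node, axis=axis)
    rng = np.random.default_rng(seed)
    work = df.T if axis == "columns" else df
    loc = list(work.index).index(node) if node in work.index else int(node)
    base = work.to_numpy(dtype=np.int64)
    exceed = 0
    for _ in range(n_perm):
        null = vaznull_sample(base, rng)
        _, _, _, dp = _dprime_array(null, loc)
        if dp >= obs.d_prime:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return DPrimeResult(node=obs.node, d=obs.d, d_min=obs.d_min, d_max=obs.d_max,
                        d_prime=obs.d_prime, p_value=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Common OTUs and ecotype co-occurrence
# ---------------------------------------------------------------------------

def select_common_otus(
    presence: PresenceMatrix,
    assignments: Mapping[str, LineageAssignment],
    k: int = 10,
    read_totals: Optional[Mapping[str, int]] = None,
) -> Tuple[List[str], List[str]]:
    """Top-k OTUs by root-sample occurrence, and their ascomycete subset.

    Ties are broken by total reads (descending, when provided) then by OTU id.
    """
    root = presence.subset("root")
    occ = root.sum(axis=0)
    totals = read_totals or {}
    ranked = sorted(
        presence.otu_ids,
        key=lambda o: (-int(occ[o]), -int(totals.get(o, 0)), o),
    )
    top = ranked[: min(k, len(ranked))]
    asco = [
        o for o in top
        if o in assignments and assignments[o].rank("phylum") == "Ascomycota"
    ]
    return top, asco


@dataclass
class CoOccurrenceSummary:
    """Per-sample ecotype flags and exclusive Fig-5-style category tallies.

    Categories partition the root samples: all_three, asc_and_ecm (no AM),
    asc_and_am (no EcM), asc_only, ecm_no_asc, am_no_asc_no_ecm, none.
    ``any_asc`` (samples with at least one common ascomycete) is a derived,
    non-exclusive tally.
    """

    flags: pd.DataFrame  # per root sample: has_common_asc, has_ecm, has_am, host
    categories: Dict[str, int]
    percentages: Dict[str, float]
    per_host: Dict[str, Dict[str, int]]
    per_host_percentages: Dict[str, Dict[str, float]]
    n_samples: int

    def host_n(self, host: str) -> int:
        return int((self.flags["host"] == host).sum())


CATEGORIES = (
    "all_three", "asc_and_ecm", "asc_and_am", "asc_only",
    "ecm_no_asc", "am_no_asc_no_ecm", "none",
)


def _categorize(asc: bool, ecm: bool, am: bool) -> str:
    if asc and ecm and am:
        return "all_three"
    if asc and ecm:
        return "asc_and_ecm"
    if asc and am:
        return "asc_and_am"
    if asc:
        return "asc_only"
    if ecm:
        return "ecm_no_asc"
    if am:
        return "am_no_asc_no_ecm"
    return "none"


def cooccurrence_summary(
    presence: PresenceMatrix,
    ecotypes: Mapping[str, str],
    common_asc: Sequence[str],
    hosts: Iterable = (),
) -> CoOccurrenceSummary:
    """Co-occurrence of the common ascomycetes with mycorrhizal ecotypes.

    ``ecotypes`` maps OTU id -> ecotype label; ``common_asc`` is the common
    ascomycete set (from :func:`select_common_otus`); ``hosts`` provides the
    per-sample host species for the per-host breakdown.
    """
    host_of = {}
    for h in hosts:
        if h is not None:
            host_of[h.sample_id] = h.species
    root = presence.subset("root")
    ecm_otus = [o for o in presence.otu_ids if ecotypes.get(o) == "ectomycorrhizal"]
    am_otus = [o for o in presence.otu_ids if ecotypes.get(o) == "arbuscular"]
    asc_set = [o for o in common_asc if o in root.columns]
    rows = []
    for s in root.index:
        r = root.loc[s]
        asc = bool(r[asc_set].any()) if asc_set else False
        ecm = bool(r[ecm_otus].any()) if ecm_otus else False
        am = bool(r[am_otus].any()) if am_otus else False
        rows.append((s, asc, ecm, am, host_of.get(s, "")))
    flags = pd.DataFrame(
        rows, columns=["sample_id", "has_common_asc", "has_ecm", "has_am", "host"]
    ).set_index("sample_id")

    def tally(sub: pd.DataFrame) -> Tuple[Dict[str, int], Dict[str, float]]:
        cats = {c: 0 for c in CATEGORIES}
        for _, row in sub.iterrows():
            cats[_categorize(row.has_common_asc, row.has_ecm, row.has_am)] += 1
        cats["any_asc"] = int(sub["has_common_asc"].sum())
        n = len(sub)
        pcts = {c: (100.0 * v / n if n else 0.0) for c, v in cats.items()}
        return cats, pcts

    categories, percentages = tally(flags)
    per_host: Dict[str, Dict[str, int]] = {}
    per_host_pct: Dict[str, Dict[str, float]] = {}
    for host in sorted({h for h in flags["host"] if h}):
        cats, pcts = tally(flags[flags["host"] == host])
        per_host[host] = cats
        per_host_pct[host] = pcts
    return CoOccurrenceSummary(
        flags=flags, categories=categories, percentages=percentages,
        per_host=per_host, per_host_percentages=per_host_pct,
        n_samples=len(flags),
    )


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def export_network(
    matrix: PlantFungusMatrix,
    assignments: Optional[Mapping[str, LineageAssignment]] = None,
    ecotypes: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list and node table of the bipartite plant-fungus web.

    Edges carry the number of root samples supporting the association; nodes
    carry type (plant/fungus), occurrence size, and for fungi the ecotype and
    a phylum letter (rendering is left to downstream tools).
    """
    edges = []
    for plant in matrix.counts.index:
        row = matrix.counts.loc[plant]
        for otu in matrix.counts.columns:
            w = int(row[otu])
            if w > 0:
                edges.append((plant, otu, w))
    edge_df = pd.DataFrame(edges, columns=["plant", "otu", "weight"])
    nodes = []
    for plant in matrix.counts.index:
        nodes.append((plant, "plant", int(matrix.samples_per_plant.get(plant, 0)),
                      "", ""))
    for otu in matrix.counts.columns:
        occ = int(matrix.counts[otu].sum())
        phylum = ""
        if assignments and otu in assignments:
            phylum = assignments[otu].rank("phylum")[:1]
        eco = ecotypes.get(otu, "unknown") if ecotypes else "unknown"
        nodes.append((otu, "fungus", occ, eco, phylum))
    node_df = pd.DataFrame(
        nodes, columns=["node", "type", "occurrence", "ecotype", "phylum_letter"]
    )
    return edge_df, node_df
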