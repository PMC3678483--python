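"""CLAM, d' specialization, vaznull nulls, common OTUs and co-occurrence."""

import math

import numpy as np
import pandas as pd
import pytest

from rootweb.community import PresenceMatrix
from rootweb.ecostats import (
    ClamConfig,
    GENERALIST,
    ROOT_SPECIALIST,
    SOIL_SPECIALIST,
    TOO_RARE,
    clam_classify,
    clam_classify_all,
    clam_pvalues,
    cooccurrence_summary,
    dprime,
    dprime_significance,
    export_network,
    select_common_otus,
    vaznull_sample,
)
from rootweb.taxonomy import LineageAssignment


CFG = ClamConfig(n_root=159, n_soil=38)


def _presence(rows, samples, otus, habitats):
    pres = pd.DataFrame(rows, index=samples, columns=otus).astype(bool)
    return PresenceMatrix(
        presence=pres,
        habitat=pd.Series(habitats, index=samples),
        retained_reads=pd.Series(100, index=samples),
    )


class TestClam:
    def test_root_only_abundant_is_root_specialist(self):
        assert clam_classify(63, 0, CFG) == ROOT_SPECIALIST

    def test_root_only_scarce_is_too_rare(self):
        assert clam_classify(18, 0, CFG) == TOO_RARE

    def test_absent_is_too_rare(self):
        assert clam_classify(0, 0, CFG) == TOO_RARE

    def test_balanced_abundant_is_generalist(self):
        # equal occurrence *fractions* in both habitats, plenty of data
        assert clam_classify(80, 19, CFG) == GENERALIST

    def test_soil_side(self):
        assert clam_classify(0, 20, CFG) == SOIL_SPECIALIST

    def test_pvalue_equals_exhaustive_binomial_tail(self):
        for yr, ys in [(63, 0), (18, 0), (10, 4), (2, 11), (40, 7)]:
            total = yr + ys
            p_root, p_soil = clam_pvalues(yr, ys, CFG)
            oracle_root = sum(
                math.comb(total, i) * CFG.p0_root**i * (1 - CFG.p0_root) ** (total - i)
                for i in range(ys + 1)
            )
            oracle_soil = sum(
                math.comb(total, i) * CFG.p0_soil**i * (1 - CFG.p0_soil) ** (total - i)
                for i in range(yr + 1)
            )
            assert p_root == pytest.approx(oracle_root, abs=1e-12)
            assert p_soil == pytest.approx(oracle_soil, abs=1e-12)

    def test_swap_symmetry(self):
        swapped = {ROOT_SPECIALIST: SOIL_SPECIALIST,
                   SOIL_SPECIALIST: ROOT_SPECIALIST,
                   GENERALIST: GENERALIST, TOO_RARE: TOO_RARE}
        mirror = ClamConfig(n_root=CFG.n_soil, n_soil=CFG.n_root)
        rng = np.random.default_rng(0)
        for _ in range(60):
            yr, ys = int(rng.integers(0, 70)), int(rng.integers(0, 30))
            assert clam_classify(ys, yr, mirror) == swapped[clam_classify(yr, ys, CFG)]

    def test_monotone_in_root_count(self):
        """Once root-specialist, adding root occurrences never demotes it."""
        for ys in (0, 3, 8):
            reached = False
            for yr in range(0, 400):
                cls = clam_classify(yr, ys, CFG)
                if reached:
                    assert cls == ROOT_SPECIALIST
                reached = reached or cls == ROOT_SPECIALIST
            assert reached

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ClamConfig(n_root=10, n_soil=10, k=0.4)
        with pytest.raises(ValueError):
            ClamConfig(n_root=10, n_soil=0)

    def test_classify_all_counts(self):
        samples = [f"r{i}" for i in range(12)] + [f"s{i}" for i in range(6)]
        habitats = ["root"] * 12 + ["soil"] * 6
        rows = np.zeros((18, 2), dtype=int)
        rows[:12, 0] = 1  # otuA in every root sample only
        rows[:, 1] = 1    # otuB everywhere
        pres = _presence(rows, samples, ["otuA", "otuB"], habitats)
        res = clam_classify_all(pres, ClamConfig(n_root=12, n_soil=6))
        assert res.table.loc["otuA", "y_root"] == 12
        assert res.table.loc["otuA", "y_soil"] == 0
        # occurrence fractions match habitat sampling: a generalist
        assert res.table.loc["otuB", "classification"] == GENERALIST
        assert res.counts[GENERALIST] == 1


class TestDPrime:
    def test_proportional_row_is_zero(self):
        # row 0 uses partners exactly in proportion to availability
        res = dprime(np.array([[2, 4], [3, 6]]), 0)
        assert res.d == pytest.approx(0.0, abs=1e-12)
        assert res.d_prime == 0.0

    def test_perfect_diagonal_is_one(self):
        mat = np.array([[5, 0], [0, 5]])
        for node in (0, 1):
            assert dprime(mat, node).d_prime == 1.0
        assert dprime(pd.DataFrame(mat), 0, axis="columns").d_prime == 1.0

    def test_greedy_extremes_match_exhaustive(self):
        from itertools import combinations

        def compositions(total, n):
            for bars in combinations(range(total + n - 1), n - 1):
                prev, out = -1, []
                for b in bars:
                    out.append(b - prev - 1)
                    prev = b
                out.append(total + n - 2 - prev)
                yield out

        def kl(alloc, q, total):
            return sum(a / total * math.log(a / total / qj)
                       for a, qj in zip(alloc, q) if a > 0)

        rng = np.random.default_rng(3)
        tested = 0
        while tested < 25:
            mat = rng.integers(0, 4, size=(3, 4))
            if (mat.sum(0) == 0).any() or (mat.sum(1) == 0).any():
                continue
            q = mat.sum(0) / mat.sum()
            row = int(rng.integers(0, 3))
            total = int(mat[row].sum())
            vals = [kl(c, q, total) for c in compositions(total, 4)]
            res = dprime(mat, row)
            assert res.d_min == pytest.approx(min(vals), abs=1e-9)
            assert res.d_max == pytest.approx(max(vals), abs=1e-9)
            assert res.d_min - 1e-12 <= res.d <= res.d_max + 1e-12
            assert 0.0 <= res.d_prime <= 1.0
            tested += 1

    def test_empty_margins_rejected(self):
        with pytest.raises(ValueError):
            dprime(np.array([[1, 0], [0, 0]]), 0)


class TestVaznull:
    def test_one_by_one_unchanged(self):
        rng = np.random.default_rng(0)
        assert vaznull_sample(np.array([[7]]), rng).tolist() == [[7]]

    def test_contracts_hold(self):
        fix = np.array([[6, 1, 0], [2, 4, 1], [0, 1, 3]])
        rng = np.random.default_rng(1)
        m, links = fix.sum(), (fix > 0).sum()
        for _ in range(500):
            r = vaznull_sample(fix, rng)
            assert r.sum() == m
            assert (r > 0).sum() == links
            assert (r.sum(axis=0) > 0).all() and (r.sum(axis=1) > 0).all()

    def test_deterministic_under_seed(self):
        fix = np.array([[6, 1, 0], [2, 4, 1], [0, 1, 3]])
        a = vaznull_sample(fix, np.random.default_rng(9))
        b = vaznull_sample(fix, np.random.default_rng(9))
        assert (a == b).all()

    def test_uncoverable_margins_rejected(self):
        with pytest.raises(ValueError):
            vaznull_sample(np.array([[1, 0], [0, 0]]), np.random.default_rng(0))


class TestDPrimeSignificance:
    MAT = pd.DataFrame(
        [[20, 10, 5], [18, 12, 6], [2, 1, 30]],
        index=["gen1", "gen2", "spec"], columns=["p1", "p2", "p3"],
    )

    def test_specialist_row_significant(self):
        res = dprime_significance(self.MAT, "spec", n_perm=400, seed=1)
        assert res.p_value < 0.05

    def test_proportional_row_not_significant(self):
        mat = pd.DataFrame([[10, 20], [5, 10], [15, 30]])
        res = dprime_significance(mat, 0, n_perm=300, seed=2)
        assert res.d_prime == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_deterministic(self):
        a = dprime_significance(self.MAT, "spec", n_perm=200, seed=7)
        b = dprime_significance(self.MAT, "spec", n_perm=200, seed=7)
        assert a.p_value == b.p_value

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            dprime_significance(self.MAT, "spec", n_perm=50)


def _lin(*names):
    return tuple(names) + ("",) * (7 - len(names))


class TestCommonOtusAndCooccurrence:
    def test_selects_by_occurrence_with_ties(self):
        occ = [63, 48, 34, 31, 28, 19, 18, 17, 8, 8, 3, 2]
        otus = [f"OTU_{i:02d}" for i in range(len(occ))]
        samples = [f"r{i}" for i in range(63)]
        rows = np.zeros((63, len(otus)), dtype=int)
        for j, n in enumerate(occ):
            rows[:n, j] = 1
        pres = _presence(rows, samples, otus, ["root"] * 63)
        assigns = {
            o: LineageAssignment(o, _lin("Fungi", "Ascomycota"), ("LCA/class",) * 2)
            for o in otus[:8]
        }
        assigns.update({
            o: LineageAssignment(o, _lin("Fungi", "Basidiomycota"), ("LCA/class",) * 2)
            for o in otus[8:]
        })
        top, asco = select_common_otus(pres, assigns, k=10)
        assert top == otus[:10]
        assert asco == otus[:8]

    def test_k_larger_than_pool(self):
        pres = _presence([[1, 1]], ["r0"], ["a", "b"], ["root"])
        top, _ = select_common_otus(pres, {}, k=10)
        assert sorted(top) == ["a", "b"]

    def test_cooccurrence_tallies_partition_samples(self):
        samples = [f"r{i}" for i in range(8)]
        otus = ["asc", "ecm", "am"]
        rows = [
            [1, 1, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1],
            [1, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 1],
        ]
        pres = _presence(rows, samples, otus, ["root"] * 8)
        ecotypes = {"ecm": "ectomycorrhizal", "am": "arbuscular"}
        summary = cooccurrence_summary(pres, ecotypes, ["asc"])
        c = summary.categories
        assert c["asc_and_ecm"] == 2
        assert c["asc_and_am"] == 1
        assert c["all_three"] == 1
        assert c["asc_only"] == 1
        assert c["ecm_no_asc"] == 1
        assert c["none"] == 1
        exclusive = [c[k] for k in
                     ("all_three", "asc_and_ecm", "asc_and_am", "asc_only",
                      "ecm_no_asc", "am_no_asc_no_ecm", "none")]
        assert sum(exclusive) == 8
        assert c["any_asc"] == 5

    def test_no_common_ascomycetes(self):
        pres = _presence([[1]], ["r0"], ["ecm"], ["root"])
        summary = cooccurrence_summary(pres, {"ecm": "ectomycorrhizal"}, [])
        assert summary.categories["any_asc"] == 0
        assert summary.percentages["asc_and_ecm"] == 0.0


class TestNetworkExport:
    def test_empty_matrix(self):
        from rootweb.community import PlantFungusMatrix
        mat = PlantFungusMatrix(
            counts=pd.DataFrame(0, index=["P"], columns=["o"], dtype=np.int64),
            samples_per_plant=pd.Series({"P": 3}),
            excluded_samples=[],
        )
        edges, nodes = export_network(mat)
        assert edges.empty
        assert len(nodes) == 2

    def test_single_edge_weight(self):
        from rootweb.community import PlantFungusMatrix
        mat = PlantFungusMatrix(
            counts=pd.DataFrame([[4]], index=["Quercus"], columns=["OTU_1"]),
            samples_per_plant=pd.Series({"Quercus": 10}),
            excluded_samples=[],
        )
        edges, nodes = export_network(mat, ecotypes={"OTU_1": "ectomycorrhizal"})
        assert len(edges) == 1
        assert edges.iloc[0].weight == 4
        fungus = nodes[nodes.type == "fungus"].iloc[0]
        assert fungus.ecotype == "ectomycorrhizal"
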