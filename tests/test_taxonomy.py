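"""Tiered databases, homolog search, strict vs relaxed LCA, priority merge."""

import numpy as np
import pytest

from rootweb.taxonomy import (
    EcotypeTable,
    HomologSet,
    LineageAssignment,
    ReferenceRecord,
    TieredDatabase,
    assign_ecotype,
    build_tier_db,
    find_homologs,
    lineage_depth,
    merge_with_priority,
    relaxed_lca,
    strict_lca,
)

from conftest import mutate, rand_seq


def _lin(*names):
    return tuple(names) + ("",) * (7 - len(names))


RUSSULA = _lin("Fungi", "Basidiomycota", "Agaricomycetes", "Russulales",
               "Russulaceae", "Russula", "Russula_sp")
LACTARIUS = _lin("Fungi", "Basidiomycota", "Agaricomycetes", "Russulales",
                 "Russulaceae", "Lactarius", "Lactarius_sp")
HELOTIALES = _lin("Fungi", "Ascomycota", "Leotiomycetes", "Helotiales")


def _db(lineages, seqs=None):
    rng = np.random.default_rng(0)
    records = {}
    for i, lin in enumerate(lineages):
        seq = seqs[i] if seqs else rand_seq(rng, 150)
        records[f"r{i}"] = ReferenceRecord(id=f"r{i}", sequence=seq, lineage=lin)
    return TieredDatabase(tier="genus", records=records)


def _hits(db, ids=None):
    ids = ids if ids is not None else list(db.records)
    return HomologSet(query_id="q", hits=[(rid, 0.95) for rid in ids])


class TestTierDatabases:
    def test_tier_membership(self):
        recs = [
            ReferenceRecord("g", "ACGT" * 40, RUSSULA),
            ReferenceRecord("c", "ACGT" * 40, HELOTIALES[:3] + ("",) * 4),
            ReferenceRecord("p", "ACGT" * 40, _lin("Fungi", "Ascomycota")),
        ]
        genus = build_tier_db(recs, "genus")
        cls = build_tier_db(recs, "class")
        assert set(genus.records) == {"g"}
        assert set(cls.records) == {"g", "c"}  # genus tier is contained in class tier

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            build_tier_db([], "order")

    def test_gappy_lineage_rejected(self):
        with pytest.raises(ValueError):
            ReferenceRecord("x", "ACGT", ("Fungi", "", "Agaricomycetes", "", "", "", ""))


class TestFindHomologs:
    def test_identity_window_rule(self):
        """Hits are records within 0.03 of the best identity, floor 0.80."""
        rng = np.random.default_rng(1)
        q = rand_seq(rng, 100)
        seqs = [mutate(q, rng, k) for k in (5, 7, 9)]  # 0.95, 0.93, 0.91
        db = _db([RUSSULA] * 3, seqs)
        hs = find_homologs(q, db)
        idents = sorted((round(i, 3) for _, i in hs.hits), reverse=True)
        assert idents == [0.95, 0.93]

    def test_single_close_record(self):
        rng = np.random.default_rng(2)
        q = rand_seq(rng, 120)
        seqs = [q] + [rand_seq(rng, 120) for _ in range(4)]
        db = _db([RUSSULA] * 5, seqs)
        hs = find_homologs(q, db)
        assert len(hs.hits) == 1 and hs.hits[0][1] == 1.0

    def test_no_record_above_floor(self):
        rng = np.random.default_rng(3)
        db = _db([RUSSULA] * 3, [rand_seq(rng, 120) for _ in range(3)])
        hs = find_homologs(rand_seq(rng, 120), db)
        assert hs.hits == []

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            find_homologs("ACGT" * 30, TieredDatabase(tier="genus", records={}))


class TestLCA:
    def test_unanimous_genus(self):
        db = _db([RUSSULA] * 10)
        assert strict_lca(_hits(db), db)[5] == "Russula"

    def test_single_discordant_hit_truncates_strict_at_family(self):
        db = _db([RUSSULA] * 9 + [LACTARIUS])
        lin = strict_lca(_hits(db), db)
        assert lin[4] == "Russulaceae" and lin[5] == ""

    def test_two_phyla_agree_only_at_kingdom(self):
        db = _db([RUSSULA] * 5 + [HELOTIALES] * 5)
        lin = strict_lca(_hits(db), db)
        assert lin[0] == "Fungi" and lin[1] == ""

    def test_relaxed_tolerates_ten_percent(self):
        db = _db([RUSSULA] * 9 + [LACTARIUS])
        lin = relaxed_lca(_hits(db), db)
        assert lin[5] == "Russula"

    def test_eighty_percent_support_fails(self):
        db = _db([RUSSULA] * 8 + [LACTARIUS] * 2)
        lin = relaxed_lca(_hits(db), db)
        assert lin[5] == ""
        assert lin[4] == "Russulaceae"

    def test_unranked_records_do_not_conflict(self):
        db = _db([RUSSULA] * 4 + [HELOTIALES[:1] + ("",) * 6] * 3)
        lin = strict_lca(_hits(db), db)
        assert lin[5] == "Russula"  # kingdom-only hits are silent below kingdom

    def test_empty_hits_unassigned(self):
        db = _db([RUSSULA])
        assert lineage_depth(strict_lca(HomologSet("q", []), db)) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_relaxed_tolerance_zero_equals_strict(self, seed):
        rng = np.random.default_rng(seed)
        pool = [RUSSULA, LACTARIUS, HELOTIALES, _lin("Fungi", "Ascomycota")]
        lineages = [pool[i] for i in rng.integers(0, len(pool), size=12)]
        db = _db(lineages)
        hits = _hits(db)
        assert relaxed_lca(hits, db, tolerance=0.0) == strict_lca(hits, db)

    @pytest.mark.parametrize("seed", range(4))
    def test_relaxed_at_least_as_deep_as_strict(self, seed):
        rng = np.random.default_rng(100 + seed)
        pool = [RUSSULA, LACTARIUS, HELOTIALES]
        lineages = [pool[i] for i in rng.integers(0, 3, size=15)]
        db = _db(lineages)
        hits = _hits(db)
        assert lineage_depth(relaxed_lca(hits, db)) >= lineage_depth(strict_lca(hits, db))


class TestMerge:
    def test_top_priority_wins_outright(self):
        merged = merge_with_priority(RUSSULA, HELOTIALES, LACTARIUS)
        assert merged.lineage == RUSSULA
        assert set(merged.methods) == {"LCA/genus"}

    def test_priority_fill_from_lower_tiers(self):
        a1 = _lin()  # genus-tier LCA found nothing
        a2 = HELOTIALES  # class tier reaches order
        a3 = _lin("Fungi", "Ascomycota", "Leotiomycetes", "Helotiales",
                  "Dermateaceae", "Cryptosporiopsis")
        merged = merge_with_priority(a1, a2, a3)
        assert merged.lineage[3] == "Helotiales"
        assert merged.lineage[5] == "Cryptosporiopsis"
        assert merged.methods[3] == "LCA/class"
        assert merged.methods[5] == "relaxed-LCA/genus"

    def test_ancestor_conflict_blocks_deeper_fill(self):
        a1 = RUSSULA[:5] + ("", "")  # truncated at family Russulaceae
        a3 = _lin("Fungi", "Basidiomycota", "Agaricomycetes", "Russulales",
                  "OtherFamily", "OtherGenus")
        merged = merge_with_priority(a1, _lin(), a3)
        assert merged.lineage[4] == "Russulaceae"
        assert merged.lineage[5] == ""  # genus under a different family rejected

    def test_no_rank_contradictions_property(self):
        rng = np.random.default_rng(7)
        pool = [RUSSULA, LACTARIUS, HELOTIALES, _lin("Fungi", "Ascomycota")]
        for _ in range(50):
            picks = [pool[i] for i in rng.integers(0, len(pool), size=3)]
            cuts = rng.integers(0, 8, size=3)
            lins = [p[:c] + ("",) * (7 - c) for p, c in zip(picks, cuts)]
            merged = merge_with_priority(*lins)
            depth = lineage_depth(merged.lineage)
            # contiguity: no gaps after the merge
            assert all(merged.lineage[i] for i in range(depth))
            assert all(not merged.lineage[i] for i in range(depth, 7))
            # every assigned rank traces back to a source whose ancestors agree
            for i in range(depth):
                assert any(
                    lin[i] == merged.lineage[i]
                    and lin[:i] == merged.lineage[:i]
                    for lin in lins
                )


class TestEcotype:
    TABLE = EcotypeTable.default()

    def test_genus_lookup(self):
        a = LineageAssignment("o1", RUSSULA, ("LCA/genus",) * 7)
        assert assign_ecotype(a, self.TABLE) == "ectomycorrhizal"

    def test_phylum_lookup(self):
        lin = _lin("Fungi", "Glomeromycota")
        a = LineageAssignment("o2", lin, ("LCA/class",) * 2)
        assert assign_ecotype(a, self.TABLE) == "arbuscular"

    def test_unlisted_order_is_unknown(self):
        a = LineageAssignment("o3", HELOTIALES, ("LCA/class",) * 4)
        assert assign_ecotype(a, self.TABLE) == "unknown"

    def test_most_specific_rank_wins(self):
        table = EcotypeTable.from_rows([
            ("Russulaceae", "family", "ectomycorrhizal"),
            ("Russula", "genus", "parasitic"),
        ])
        a = LineageAssignment("o4", RUSSULA, ("LCA/genus",) * 7)
        assert assign_ecotype(a, table) == "parasitic"
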