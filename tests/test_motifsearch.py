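"""Database curation, motif search vs a brute-force oracle, post-processing."""

import itertools
import random

import numpy as np
import pytest

from crossalpha.forge import (DecoyDatabaseSpec, build_ideal_helix,
                              make_decoy_database)
from crossalpha.helixgeom import superpose
from crossalpha.motifsearch import (AA20, DatabaseFilter, MotifMatch,
                                    SearchDatabase, cluster_chains,
                                    define_motif, divergence_curve,
                                    filter_database, load_motif, logo_counts,
                                    redundancy_filter, save_motif,
                                    search_motif, select_nonredundant_biounits,
                                    sequence_identity)
from crossalpha.structio import Atom, Chain, Residue, Structure


def tiny_structure(sid, n_residues=1, n_chains=1, resolution=2.0,
                   method="X-RAY DIFFRACTION", **meta):
    chains = []
    per_chain = max(1, n_residues // n_chains)
    left = n_residues
    for ci in range(n_chains):
        n = per_chain if ci < n_chains - 1 else left
        left -= n
        chains.append(Chain(
            "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"[ci],
            [Residue(i + 1, "A", [Atom("CA", "C", [float(i), 0.0, float(ci)])])
             for i in range(n)]))
    s = Structure(sid, chains)
    s.meta.update({"resolution": resolution, "method": method, **meta})
    return s


class TestFilterDatabase:
    def test_resolution_boundary_is_inclusive(self):
        kept, _ = filter_database([tiny_structure("s", resolution=2.6)],
                                  DatabaseFilter())
        assert len(kept) == 1

    def test_residue_count_boundary(self):
        kept, reasons = filter_database(
            [tiny_structure("big", n_residues=5001),
             tiny_structure("ok", n_residues=5000)], DatabaseFilter())
        assert [s.id for s in kept] == ["ok"]
        assert reasons["too-many-residues"] == 1

    def test_each_violation_counted(self):
        good = [tiny_structure(f"g{i}") for i in range(7)]
        bad = [tiny_structure("r", resolution=3.0),
               tiny_structure("m", resolution=None),
               tiny_structure("c", n_residues=27, n_chains=27)]
        bad[1].meta.pop("resolution")
        kept, reasons = filter_database(good + bad, DatabaseFilter())
        assert len(kept) == 7
        assert reasons["resolution"] == 1
        assert reasons["missing-metadata"] == 1
        assert reasons["too-many-chains"] == 1

    def test_non_xray_rejected_only_when_required(self):
        em = tiny_structure("em", method="ELECTRON MICROSCOPY")
        assert filter_database([em], DatabaseFilter())[0] == []
        assert filter_database([em], DatabaseFilter(xray_only=False))[0] == [em]


class TestClusterChains:
    def test_identical_sequences_share_a_cluster(self):
        ids = cluster_chains(["AEILKAK", "AEILKAK"])
        assert ids[0] == ids[1]

    def test_unrelated_random_sequences_split(self):
        rng = random.Random(11)
        a = "".join(rng.choice(AA20) for _ in range(100))
        b = "".join(rng.choice(AA20) for _ in range(100))
        assert sequence_identity(a, b) < 0.3
        ids = cluster_chains([a, b])
        assert ids[0] != ids[1]

    def test_sixty_percent_identity_joins_at_half_threshold(self):
        rng = random.Random(7)
        a = "".join(rng.choice(AA20) for _ in range(50))
        b = list(a)
        for pos in rng.sample(range(50), 20):  # mutate 40% of positions
            b[pos] = next(x for x in AA20 if x != a[pos])
        b = "".join(b)
        assert sequence_identity(a, b) == pytest.approx(0.6, abs=0.01)
        ids = cluster_chains([a, b], identity=0.5)
        assert ids[0] == ids[1]

    def test_empty_input(self):
        assert cluster_chains([]) == []


class TestNonredundantBiounits:
    def test_superset_eliminates_subset(self):
        a, b = tiny_structure("a"), tiny_structure("b", n_chains=2)
        kept = select_nonredundant_biounits([a, b],
                                            {"a": (0,), "b": (0, 1)})
        assert [s.id for s in kept] == ["b"]

    def test_equal_sets_keep_better_resolution(self):
        a = tiny_structure("a", resolution=2.5)
        b = tiny_structure("b", resolution=2.0)
        kept = select_nonredundant_biounits([a, b], {"a": (0,), "b": (0,)})
        assert [s.id for s in kept] == ["b"]

    def test_disjoint_sets_both_retained(self):
        a, b = tiny_structure("a"), tiny_structure("b")
        kept = select_nonredundant_biounits([a, b], {"a": (0,), "b": (1,)})
        assert {s.id for s in kept} == {"a", "b"}

    def test_multiset_counts_matter(self):
        # two copies of a cluster are not covered by a single copy
        a, b = tiny_structure("a", n_chains=2), tiny_structure("b")
        kept = select_nonredundant_biounits([a, b], {"a": (0, 0), "b": (0,)})
        assert [s.id for s in kept] == ["a"]

    def test_order_invariance(self):
        structs = [tiny_structure(f"s{i}", resolution=2.0 + 0.1 * i)
                   for i in range(6)]
        clusters = {"s0": (0,), "s1": (0, 1), "s2": (2,), "s3": (2,),
                    "s4": (3, 4), "s5": (4,)}
        baseline = {s.id for s in select_nonredundant_biounits(structs, clusters)}
        rng = random.Random(3)
        for _ in range(5):
            shuffled = structs[:]
            rng.shuffle(shuffled)
            got = {s.id for s in select_nonredundant_biounits(shuffled, clusters)}
            assert got == baseline


class TestDefineMotif:
    def test_two_segment_clasp_motif_shape(self, clasp_motif):
        assert len(clasp_motif.segments) == 2
        assert [s.length for s in clasp_motif.segments] == [7, 5]
        assert clasp_motif.n_residues == 12
        assert clasp_motif.n_atoms == 48
        # RxxxR: arginines at segment positions 1 and 5
        assert clasp_motif.segments[0].sequence[0] == "R"
        assert clasp_motif.segments[0].sequence[4] == "R"

    def test_control_motif_same_size(self, control_motif):
        assert [s.length for s in control_motif.segments] == [7, 5]

    def test_zero_length_segment_rejected(self, clasp_filament):
        with pytest.raises(ValueError, match="zero-length"):
            define_motif(clasp_filament,
                         [(clasp_filament.chains[0].chain_id, 6, 0)])

    def test_missing_backbone_atom_named(self):
        res = [Residue(i, "A", [Atom("N", "N", [0.0, 0.0, i]),
                                Atom("CA", "C", [1.0, 0.0, i]),
                                Atom("C", "C", [2.0, 0.0, i])])
               for i in range(1, 7)]  # no carbonyl O
        s = Structure("broken", [Chain("A", res)])
        with pytest.raises(ValueError, match="O"):
            define_motif(s, [("A", 1, 5)])

    def test_json_round_trip(self, tmp_path, clasp_motif):
        p = tmp_path / "motif.json"
        save_motif(clasp_motif, p)
        back = load_motif(p)
        assert [s.sequence for s in back.segments] == \
            [s.sequence for s in clasp_motif.segments]
        for sa, sb in zip(back.segments, clasp_motif.segments):
            assert np.allclose(sa.backbone, sb.backbone)


# ---------------------------------------------------------------------------
# search vs brute force
# ---------------------------------------------------------------------------

def brute_force_search(entries, q, cutoff):
    """Exhaustive enumeration of all window placements (the oracle)."""
    hits = []
    q_stacked = q.stacked()
    for entry in entries:
        seg_windows = []
        for seg in q.segments:
            wins = []
            for chain in entry.chains:
                res = [r for r in chain.residues
                       if all(r.has_atom(n) for n in ("N", "CA", "C", "O"))]
                for i in range(len(res) - seg.length + 1):
                    window = res[i:i + seg.length]
                    if window[-1].seq_id - window[0].seq_id != seg.length - 1:
                        continue
                    coords = np.array([[r.atom(n).position
                                        for n in ("N", "CA", "C", "O")]
                                       for r in window]).reshape(-1, 3)
                    wins.append((chain.chain_id, window[0].seq_id, coords))
            seg_windows.append(wins)
        for combo in itertools.product(*seg_windows):
            overlap = False
            for (sa, sb) in itertools.combinations(range(len(combo)), 2):
                ca, ia, _ = combo[sa]
                cb, ib, _ = combo[sb]
                la, lb = q.segments[sa].length, q.segments[sb].length
                if ca == cb and ia < ib + lb and ib < ia + la:
                    overlap = True
                    break
            if overlap:
                continue
            w = np.concatenate([c[2] for c in combo])
            r = superpose(w, q_stacked).rmsd
            if r <= cutoff:
                hits.append((entry.id, tuple((c[0], c[1]) for c in combo),
                             float(r)))
    return sorted(hits)


@pytest.fixture(scope="module")
def decoy_db(clasp_motif):
    return make_decoy_database(DecoyDatabaseSpec(
        12, (25, 40), planted_motif=clasp_motif, plant_sigma=0.3, seed=21))


class TestSearchMotif:
    def test_self_match_is_rank_one_at_zero(self, clasp_filament, clasp_motif):
        matches = search_motif([clasp_filament], clasp_motif, 1.0)
        assert matches
        assert matches[0].rmsd <= 1e-9
        a = clasp_filament.chains[0].chain_id
        b = clasp_filament.chains[1].chain_id
        assert set(matches[0].placements) == {(a, 6), (b, 32)}

    def test_pruned_search_equals_brute_force(self, decoy_db, clasp_motif):
        got = search_motif(decoy_db, clasp_motif, 1.0)
        got_set = sorted((m.entry_id, tuple(m.placements), m.rmsd)
                         for m in got)
        oracle = brute_force_search(decoy_db, clasp_motif, 1.0)
        assert [(e, p) for e, p, _ in got_set] == [(e, p) for e, p, _ in oracle]
        for (_, _, r1), (_, _, r2) in zip(got_set, oracle):
            assert r1 == pytest.approx(r2, abs=1e-6)

    def test_matches_sorted_by_rmsd(self, decoy_db, clasp_motif):
        rmsds = [m.rmsd for m in search_motif(decoy_db, clasp_motif, 1.5)]
        assert rmsds == sorted(rmsds)

    def test_query_longer_than_any_chain_gives_empty(self, clasp_filament):
        helix = build_ideal_helix("AEILKAKAEILKAKAEILKAK")
        q = define_motif(helix, [("A", 1, 20)])
        short = build_ideal_helix("AEILK")
        assert search_motif([short], q, 1.0) == []

    def test_placements_never_overlap(self, decoy_db, clasp_motif):
        for m in search_motif(decoy_db, clasp_motif, 1.5):
            (ca, ia), (cb, ib) = m.placements
            if ca == cb:
                assert ia + 7 <= ib or ib + 5 <= ia


class TestRedundancyFilter:
    def test_identical_flanked_sequences_collapse_to_best(self, decoy_db,
                                                          clasp_motif):
        planted = [s for s in decoy_db if s.meta["planted"]][0]
        m1 = search_motif([planted], clasp_motif, 1.0)[0]
        m2 = MotifMatch(m1.entry_id, m1.placements, m1.rmsd + 0.2, m1.sequences)
        kept = redundancy_filter([m2, m1], decoy_db)
        assert kept == [m1]

    def test_idempotent(self, decoy_db, clasp_motif):
        matches = search_motif(decoy_db, clasp_motif, 1.5)
        once = redundancy_filter(matches, decoy_db)
        twice = redundancy_filter(once, decoy_db)
        assert [m.sort_key() for m in twice] == [m.sort_key() for m in once]

    def test_unrelated_sequences_all_kept(self, decoy_db, clasp_motif):
        # matches on distinct random-sequence decoys share ~5% identity
        matches = search_motif(decoy_db, clasp_motif, 1.5)
        by_entry = {}
        for m in matches:
            by_entry.setdefault(m.entry_id, m)
        distinct = list(by_entry.values())
        kept = redundancy_filter(distinct, decoy_db)
        assert len(kept) == len(distinct)


class TestCurves:
    def test_empty_matches_empty_curve(self):
        c = divergence_curve([])
        assert len(c.rmsds) == 0

    def test_all_zero_rmsd_steps_to_k(self):
        ms = [MotifMatch("e", [("A", 1)], 0.0, ["AAA"]) for _ in range(4)]
        c = divergence_curve(ms)
        assert c.count_below(0.0) == 4
        assert list(c.counts) == [1, 2, 3, 4]

    def test_monotone_under_added_matches(self, decoy_db, clasp_motif):
        matches = search_motif(decoy_db, clasp_motif, 1.5)
        part = divergence_curve(matches[: len(matches) // 2])
        full = divergence_curve(matches)
        for r in np.linspace(0, 1.5, 20):
            assert full.count_below(r) >= part.count_below(r)


class TestLogoCounts:
    def test_single_match_one_count_per_position(self):
        m = MotifMatch("e", [("A", 1)], 0.0, ["RAEAR"])
        lc = logo_counts([m])
        assert lc.counts.values.sum() == 5
        assert lc.dominant(1) == "R"
        assert lc.dominant(5) == "R"

    def test_column_sums_equal_match_count(self, decoy_db, clasp_motif):
        matches = search_motif(decoy_db, clasp_motif, 1.5)
        lc = logo_counts(matches, top_k=len(matches))
        assert (lc.counts.sum(axis=1) == len(matches)).all()

    def test_planted_arginines_dominate(self, clasp_motif):
        db = make_decoy_database(DecoyDatabaseSpec(
            12, (25, 35), planted_motif=clasp_motif, plant_sigma=0.2,
            n_planted=8, seed=33))
        matches = search_motif(db, clasp_motif, 1.0)
        lc = logo_counts(matches, top_k=len(matches))
        # query positions 1 and 5 carry the RxxxR arginines
        assert lc.dominant(1) == "R"
        assert lc.dominant(5) == "R"


class TestSearchDatabaseBuild:
    def test_end_to_end_curation(self, decoy_db):
        db = SearchDatabase.build(decoy_db, DatabaseFilter(xray_only=False))
        assert db.entries
        assert set(db.chain_clusters) == {s.id for s in db.entries}
        for s in db.entries:
            assert len(db.chain_clusters[s.id]) == len(s.chains)
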