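"""Read filtering, clustering (vs brute-force oracle), labeling, folds."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mlpd import seqdata
from mlpd._util import derive_rng, random_sequences
from mlpd.seqdata import (
    AMBIGUOUS,
    NEGATIVE,
    POSITIVE,
    CountTable,
    PoolInfo,
    StringencyLabels,
    candidate_neighbors,
    cluster_all_pairs,
    cluster_with_projection,
    concordance,
    connected_components,
    filter_and_extract,
    kmer_signature,
    label_pools,
    levenshtein,
    normalize_counts,
    split_folds,
    superbin,
    verify_neighbors,
)

FP, RP = "AGCAGCACAGAGGTCAGATG", "CCTATGCGTGCTACCGTGAA"


def _mutated_family(rng, n_members=4, n_edits=3, length=40):
    """A base sequence plus members within a few substitutions of it."""
    base = random_sequences(1, length, rng)[0]
    family = [base]
    for _ in range(n_members - 1):
        s = list(base)
        for p in rng.choice(length, size=n_edits, replace=False):
            s[p] = "ACGT"[int(rng.integers(0, 4))]
        family.append("".join(s))
    return family


def brute_force_clusters(seqs, max_edit=5):
    """Independent O(n^2) oracle: explicit Levenshtein graph + components."""
    g = nx.Graph()
    g.add_nodes_from(seqs)
    for a, b in itertools.combinations(seqs, 2):
        if 0 <= levenshtein(a, b) <= max_edit:
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def partitions_equal(assignment, oracle_components):
    got = {}
    for seq, cid in assignment.items():
        got.setdefault(cid, set()).add(seq)
    return sorted(map(sorted, got.values())) == sorted(map(sorted, oracle_components))


class TestFilterAndExtract:
    def test_clean_read_kept(self):
        insert = "ACGT" * 10
        read = (FP + insert + RP, [40] * (len(FP) + 40 + len(RP)))
        kept, rejects = filter_and_extract([read], FP, RP)
        assert kept == [insert] and not rejects

    @pytest.mark.parametrize(
        "insert,reason",
        [
            ("ACGT" * 9 + "ACG", "length"),  # 39 nt
            ("ACGT" * 9 + "ACGN", "ambiguous"),
            ("ACGT" * 10, "quality"),
        ],
    )
    def test_rejected_reads_tallied(self, insert, reason):
        q = 10 if reason == "quality" else 40
        read = (FP + insert + RP, [q] * (len(FP) + len(insert) + len(RP)))
        kept, rejects = filter_and_extract([read], FP, RP)
        assert not kept and rejects == {reason: 1}

    def test_missing_primer_dropped(self):
        kept, rejects = filter_and_extract(["ACGT" * 20], FP, RP)
        assert not kept and rejects == {"primer": 1}


class TestKmerSignature:
    def test_homopolymer_single_entry(self):
        assert kmer_signature("A" * 40) == {"AAAAAA": 35}

    def test_entries_sum_to_positions(self, random_40mers):
        for s in random_40mers[:20]:
            assert sum(kmer_signature(s).values()) == 35

    def test_reverse_gives_different_signature(self, rng):
        s = random_sequences(1, 40, rng)[0]
        assert kmer_signature(s) != kmer_signature(s[::-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_signature("ACGTA", k=6)


class TestCandidateNeighbors:
    def test_identical_sequences_are_candidates(self):
        sigs = [kmer_signature("ACGT" * 10)] * 2
        assert candidate_neighbors(sigs) == [(0, 1)]

    def test_disjoint_kmer_sets_never_candidates(self):
        sigs = [kmer_signature("A" * 40), kmer_signature("C" * 40)]
        assert candidate_neighbors(sigs) == []

    def test_superset_of_levenshtein_neighborhood(self, rng):
        # inverted-index candidates must contain every edit<=5 pair
        seqs = random_sequences(420, 40, rng)
        for _ in range(20):
            seqs += _mutated_family(rng)
        seqs = sorted(set(seqs))[:500]
        sigs = [kmer_signature(s) for s in seqs]
        cands = set(candidate_neighbors(sigs))
        for i, j in itertools.combinations(range(len(seqs)), 2):
            if 0 <= levenshtein(seqs[i], seqs[j], 5) <= 5:
                assert (i, j) in cands


class TestVerifyNeighbors:
    def test_inclusive_at_distance_five(self):
        a = "A" * 40
        b = "C" * 5 + "A" * 35  # distance exactly 5
        c = "C" * 6 + "A" * 34  # distance 6
        edges = verify_neighbors([(0, 1), (0, 2), (0, 0)], [a, b, c])
        assert (0, 1) in edges and (0, 2) not in edges and (0, 0) in edges


class TestConnectedComponents:
    def test_transitive_chain_merges(self):
        # a-b and b-c linked, a-c far apart: one component regardless
        ca = connected_components([(0, 1), (1, 2)], ["AAA", "AAC", "ACC"])
        assert len(set(ca.assignment.values())) == 1

    def test_no_edges_all_singletons(self, random_40mers):
        ca = connected_components([], random_40mers[:10])
        assert ca.n_clusters == 10

    def test_matches_brute_force_on_random_sequences(self, rng):
        seqs = random_sequences(150, 40, rng)
        for _ in range(10):
            seqs += _mutated_family(rng)
        seqs = sorted(set(seqs))[:200]
        ca = cluster_all_pairs(seqs)
        assert partitions_equal(ca.assignment, brute_force_clusters(seqs))

    def test_representative_is_highest_count_then_lexicographic(self):
        seqs = ["AAAA", "AAAC", "AAAG"]
        ca = connected_components([(0, 1), (1, 2)], seqs, counts={"AAAC": 5, "AAAA": 5})
        assert ca.representatives[0] == "AAAA"  # tie on count, lexicographic


class TestClusterWithProjection:
    def test_cap_at_least_n_equals_all_pairs(self, rng):
        seqs = random_sequences(80, 40, rng) + _mutated_family(rng)
        counts = {s: int(rng.integers(1, 5)) for s in seqs}
        full = cluster_all_pairs(sorted(counts), counts)
        proj = cluster_with_projection(counts, all_pairs_cap=len(counts))
        assert partitions_equal(proj.assignment, brute_force_clusters(sorted(counts)))
        assert partitions_equal(proj.assignment, [set(m) for m in full.members().values()])

    def test_singleton_projected_into_nearby_cluster(self, rng):
        base = random_sequences(1, 40, rng)[0]
        near = base[:-1] + ("A" if base[-1] != "A" else "C")
        far = random_sequences(1, 40, rng)[0]
        counts = {base: 10, far: 10, near: 1}
        ca = cluster_with_projection(counts, all_pairs_cap=2)
        assert ca.assignment[near] == ca.assignment[base]
        assert ca.phase[near] == "projected"

    def test_tie_goes_to_smaller_distance_then_smaller_cluster_id(self):
        a = "A" * 40
        b = "C" * 10 + "A" * 30  # far from a
        query_close_to_a = "A" * 39 + "C"  # d=1 to a, far from b
        counts = {a: 5, b: 5, query_close_to_a: 1}
        ca = cluster_with_projection(counts, all_pairs_cap=2)
        assert ca.assignment[query_close_to_a] == ca.assignment[a]
        # equidistant between two singleton clusters: smaller cluster id wins
        x = "A" * 20 + "C" * 20
        y = "A" * 20 + "G" * 20
        q = "A" * 20 + "C" * 10 + "G" * 10  # distance 10 to both
        ca2 = cluster_with_projection({x: 5, y: 5, q: 1}, all_pairs_cap=2, max_edit=10)
        cid_x, cid_y = ca2.assignment[x], ca2.assignment[y]
        assert ca2.assignment[q] == min(cid_x, cid_y)

    def test_unmatched_projection_becomes_new_singleton(self, rng):
        a, b = random_sequences(2, 40, rng)
        ca = cluster_with_projection({a: 5, b: 1}, all_pairs_cap=1)
        assert ca.assignment[a] != ca.assignment[b]


def _two_level_table(counts_pos1, counts_neg1, counts_pos2, counts_neg2, coverage=1000.0):
    pools = [
        PoolInfo("R1_256nM_pos", 1, 256.0, "pos", sum(counts_pos1.values()), coverage),
        PoolInfo("R1_256nM_neg", 1, 256.0, "neg", sum(counts_neg1.values()), coverage),
        PoolInfo("R1_64nM_pos", 1, 64.0, "pos", sum(counts_pos2.values()), coverage),
        PoolInfo("R1_64nM_neg", 1, 64.0, "neg", sum(counts_neg2.values()), coverage),
    ]
    return CountTable.from_counts(
        {
            "R1_256nM_pos": counts_pos1,
            "R1_256nM_neg": counts_neg1,
            "R1_64nM_pos": counts_pos2,
            "R1_64nM_neg": counts_neg2,
        },
        pools,
    )


class TestNormalizeCounts:
    def test_fractions(self):
        t = _two_level_table({"A" * 40: 30, "C" * 40: 70}, {"A" * 40: 10}, {"C" * 40: 5}, {"A" * 40: 5})
        f = normalize_counts(t)
        assert f.loc["A" * 40, "R1_256nM_pos"] == pytest.approx(0.3)
        assert np.allclose(f.sum(axis=0), 1.0)

    def test_empty_pool_warns(self):
        t = _two_level_table({"A" * 40: 3}, {}, {"A" * 40: 1}, {"C" * 40: 1})
        with pytest.warns(UserWarning, match="empty pools"):
            f = normalize_counts(t)
        assert (f["R1_256nM_neg"] == 0).all()


class TestLabelPools:
    def test_coverage_instance_from_screen_design(self):
        # expected coverage 6865 reads -> 20% threshold 1373
        s, other = "A" * 40, "C" * 40
        pools = [
            PoolInfo("R1_256nM_pos", 1, 256.0, "pos", 1373 + 5000, 6865.0),
            PoolInfo("R1_256nM_neg", 1, 256.0, "neg", 5000, 6865.0),
        ]
        t = CountTable.from_counts(
            {"R1_256nM_pos": {s: 1373, other: 5000}, "R1_256nM_neg": {other: 5000}}, pools
        )
        labels = label_pools(t)
        assert labels.df.loc[s, 256.0] == POSITIVE

    def test_low_counts_ambiguous(self):
        t = _two_level_table({"A" * 40: 10}, {"A" * 40: 10}, {"A" * 40: 10}, {"A" * 40: 10})
        labels = label_pools(t)
        assert (labels.df.loc["A" * 40] == AMBIGUOUS).all()

    def test_missing_paired_pool_rejected(self):
        pools = [PoolInfo("R1_64nM_pos", 1, 64.0, "pos", 5, 10.0)]
        t = CountTable.from_counts({"R1_64nM_pos": {"A" * 40: 5}}, pools)
        with pytest.raises(ValueError, match="paired"):
            label_pools(t)

    def test_noiseless_simulation_labels_match_oracle_thresholds(self, oracle, train_ladder):
        from mlpd import pd_sim

        config = pd_sim.SimConfig(library_size=250, noise_cv=0.0)
        exp = pd_sim.simulate_experiment(config, train_ladder, oracle, seed=12)
        labels = label_pools(exp.table)
        for seq in exp.library:
            kd = oracle.kd(seq)
            for conc in labels.concentrations:
                got = labels.df.loc[seq, conc]
                if got == AMBIGUOUS:
                    continue
                expected = POSITIVE if kd <= 2 * conc else NEGATIVE
                assert got == expected

    def test_deterministic(self, small_experiment):
        a = label_pools(small_experiment.table)
        b = label_pools(small_experiment.table)
        assert a.df.equals(b.df)


def _labels(rows):
    df = pd.DataFrame(rows).T
    df.columns = [1024.0, 256.0, 64.0]
    return StringencyLabels(df)


class TestSuperBin:
    def test_level_mapping(self):
        labels = _labels(
            {
                "s_allneg": [NEGATIVE, NEGATIVE, NEGATIVE],
                "s_allpos": [POSITIVE, POSITIVE, POSITIVE],
                "s_one": [POSITIVE, NEGATIVE, NEGATIVE],
                "s_one_borderline": [POSITIVE, AMBIGUOUS, NEGATIVE],
                "s_borderline0": [AMBIGUOUS, NEGATIVE, NEGATIVE],
            }
        )
        levels = superbin(labels)
        assert levels["s_allneg"] == 0
        assert levels["s_allpos"] == 6
        assert levels["s_one"] == 2
        assert levels["s_one_borderline"] == 3
        assert levels["s_borderline0"] == 1

    def test_conflict_and_all_ambiguous_excluded(self):
        labels = _labels(
            {
                "s_conflict": [NEGATIVE, POSITIVE, NEGATIVE],
                "s_skip": [POSITIVE, NEGATIVE, POSITIVE],
                "s_noinfo": [AMBIGUOUS, AMBIGUOUS, AMBIGUOUS],
            }
        )
        levels = superbin(labels)
        assert len(levels) == 0

    def test_monotone_in_passed_stringencies(self):
        # turning any non-conflicting label into a pass never lowers the level
        states = [POSITIVE, NEGATIVE, AMBIGUOUS]
        for row in itertools.product(states, repeat=3):
            base = superbin(_labels({"s": list(row)}))
            for j in range(3):
                if row[j] == POSITIVE:
                    continue
                upgraded = list(row)
                upgraded[j] = POSITIVE
                up = superbin(_labels({"s": upgraded}))
                if "s" in base.index and "s" in up.index:
                    assert up["s"] >= base["s"]


class TestConcordance:
    def test_noiseless_simulation_fully_nested(self, oracle, train_ladder):
        from mlpd import pd_sim

        config = pd_sim.SimConfig(library_size=250, noise_cv=0.0)
        exp = pd_sim.simulate_experiment(config, train_ladder, oracle, seed=13)
        assert (concordance(label_pools(exp.table)) == 1.0).all()

    def test_single_stringency_vacuous(self):
        df = pd.DataFrame({64.0: [POSITIVE, NEGATIVE]}, index=["A" * 40, "C" * 40])
        assert (concordance(StringencyLabels(df)) == 1.0).all()

    def test_one_violator_among_ten(self):
        rows = {f"s{i}": [POSITIVE, POSITIVE, NEGATIVE] for i in range(9)}
        rows["violator"] = [NEGATIVE, POSITIVE, NEGATIVE]
        c = concordance(_labels(rows))
        assert c[256.0] == pytest.approx(0.9)


class TestSplitFolds:
    def test_round_robin_sizes(self, random_40mers):
        ca = connected_components([], random_40mers[:10])
        split = split_folds(ca, n_folds=5, seed=1)
        sizes = pd.Series(list(split.fold_of_cluster.values())).value_counts()
        assert (sizes == 2).all()

    def test_giant_cluster_warns(self):
        seqs = ["AAAA", "AAAC", "AAAG"]
        ca = connected_components([(0, 1), (1, 2)], seqs)
        with pytest.warns(UserWarning, match="folds"):
            split_folds(ca, n_folds=5, seed=0)

    def test_no_close_pair_spans_train_test(self, rng):
        seqs = random_sequences(160, 40, rng)
        for _ in range(10):
            seqs += _mutated_family(rng)
        seqs = sorted(set(seqs))[:200]
        ca = cluster_all_pairs(seqs)
        split = split_folds(ca, seed=3)
        train, test = split.train_test_sequences()
        for a in train:
            for b in test:
                assert not (0 <= levenshtein(a, b, 5) <= 5)

    def test_deterministic(self, random_40mers):
        ca = connected_components([], random_40mers[:20])
        a = split_folds(ca, seed=5)
        b = split_folds(ca, seed=5)
        assert a.fold_of_cluster == b.fold_of_cluster


def test_labels_tsv_round_trip(tmp_path, small_labels):
    path = tmp_path / "labels.tsv"
    small_labels.write(path)
    loaded = StringencyLabels.read(path)
    assert loaded.df.equals(small_labels.df)


def test_cluster_tsv_round_trip(tmp_path, random_40mers):
    ca = cluster_all_pairs(random_40mers[:30])
    path = tmp_path / "clusters.tsv"
    ca.write(path)
    loaded = seqdata.ClusterAssignment.read(path)
    assert loaded.assignment == ca.assignment
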