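"""Mononucleotide-repeat scanning, abundances, filtering and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyorigin.mnr import (
    FEATURES,
    MNRAbundanceMatrix,
    abundance_matrix,
    bootstrap_clusters,
    cluster_samples,
    filter_features,
    mnr_distance,
    scan_mnr,
)


def brute_force_scan(seq):
    """Independent oracle: explicit enumeration of maximal runs."""
    seq = seq.upper()
    counts = {f: 0 for f in FEATURES}
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        L = j - i
        if seq[i] != "N" and 3 <= L <= 20:
            counts[f"{seq[i]}{L}"] += 1
        i = j
    return counts


class TestScanMnr:
    def test_no_runs(self):
        assert scan_mnr("ACGTACGT").sum() == 0

    def test_hand_example(self):
        c = scan_mnr("AAAATTTCCCCCCG")
        assert c["A4"] == 1 and c["T3"] == 1 and c["C6"] == 1
        assert c.sum() == 3

    def test_long_run_excluded_by_default_or_capped(self):
        seq = "A" * 25
        assert scan_mnr(seq).sum() == 0
        capped = scan_mnr(seq, long_run_policy="cap")
        assert capped["A20"] == 1 and capped.sum() == 1

    def test_n_breaks_runs(self):
        c = scan_mnr("AAANAAA")
        assert c["A3"] == 2

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            scan_mnr("AAAXAAA")

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"),
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04], size=2000))
        assert scan_mnr(seq).to_dict() == brute_force_scan(seq)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_reverse_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_mnr(seq)
        rev = scan_mnr(rc)
        swap = str.maketrans("ACGT", "TGCA")
        for f in FEATURES:
            assert fwd[f] == rev[f[0].translate(swap) + f[1:]]


class TestAbundance:
    def test_coverage_vs_count_convention(self):
        seq = "AAAAA" + "CGTA" * 23 + "CGT"  # length 100, one (A,5) run
        assert len(seq) == 100
        cov = abundance_matrix([("x", seq)])
        cnt = abundance_matrix([("x", seq)], convention="count")
        assert cov.abundance.loc["x", "A5"] == pytest.approx(5.0)
        assert cnt.abundance.loc["x", "A5"] == pytest.approx(1.0)

    def test_coverage_bounded_by_sequence_length(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("AT"), size=5000))
        m = abundance_matrix([("x", seq)])
        run_len = np.array([int(f[1:]) for f in FEATURES])
        assert (m.counts.loc["x"].values * run_len).sum() <= 5000

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            abundance_matrix([("x", "")])


class TestFilterFeatures:
    def _matrix(self, abundance):
        ab = pd.DataFrame(abundance)
        return MNRAbundanceMatrix(
            counts=(ab > 0).astype(int), abundance=ab,
            seq_lengths=pd.Series(100, index=ab.index))

    def test_zero_and_constant_features_dropped(self):
        m = self._matrix({
            "A3": [0.0, 0.0, 0.0, 0.0, 0.0],       # zero -> dropped
            "A4": [2.0, 2.0, 2.0, 2.0, 2.0],       # constant -> dropped
            "C3": [1.0, 2.0, 1.0, 2.0, 1.0],
        })
        out = filter_features(m)
        assert out.features == ["C3"]

    def test_hand_enumerated_five_by_ten(self):
        rng = np.random.default_rng(0)
        data = {f"A{k}": rng.random(5).round(3) for k in range(3, 8)}  # 5 vary
        data.update({f"C{k}": [1.5] * 5 for k in range(3, 6)})  # 3 constant
        data.update({f"G{k}": [0.0] * 5 for k in range(3, 5)})  # 2 zero
        out = filter_features(self._matrix(data))
        assert len(out.features) == 5

    def test_idempotent(self):
        m = self._matrix({
            "A3": [0.0, 0.0, 0.0], "A4": [1.0, 2.0, 3.0], "T5": [4.0, 4.0, 4.0],
        })
        once = filter_features(m)
        twice = filter_features(once)
        assert once.features == twice.features
        assert once.abundance.equals(twice.abundance)

    def test_warns_when_empty(self):
        m = self._matrix({"A3": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning):
            out = filter_features(m)
        assert out.features == []


class TestDistanceAndClustering:
    def _abundance(self, rows, index=None):
        ab = pd.DataFrame(
            rows, index=index or [f"g{i}" for i in range(len(rows))],
            columns=[f"A{k+3}" for k in range(len(rows[0]))], dtype=float)
        return MNRAbundanceMatrix(
            counts=ab.astype(int), abundance=ab,
            seq_lengths=pd.Series(100, index=ab.index))

    def test_identical_rows_zero_distance(self):
        m = self._abundance([[1, 2], [1, 2], [3, 0]])
        D = mnr_distance(m)
        assert D.iloc[0, 1] == 0.0

    def test_three_four_five(self):
        m = self._abundance([[0, 0], [3, 4]])
        assert mnr_distance(m).iloc[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        rows = rng.random((6, 10))
        m = self._abundance(rows.tolist())
        D = mnr_distance(m).values
        for i in range(6):
            for j in range(6):
                expect = np.sqrt(((rows[i] - rows[j]) ** 2).sum())
                assert D[i, j] == pytest.approx(expect)

    def test_identical_distance_profiles_merge_first(self):
        # identical distance-matrix rows have Pearson correlation 1 -> d* = 0
        rng = np.random.default_rng(14)
        rows = rng.random((6, 8)) * 3
        rows[1] = rows[0]  # g1 duplicates g0: their distance profiles agree
        m = self._abundance(rows.tolist())
        res = cluster_samples(mnr_distance(m))
        first_merge = res.cluster_leaf_sets()[0]
        assert first_merge == frozenset(["g0", "g1"])

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        m = self._abundance(rng.random((8, 12)).tolist())
        res = cluster_samples(mnr_distance(m))
        h = res.heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_planted_partition_top_split(self):
        rng = np.random.default_rng(6)
        a = rng.random((4, 20)) + 5.0
        b = rng.random((4, 20))
        m = self._abundance(np.vstack([a, b]).tolist())
        res = cluster_samples(mnr_distance(m))
        top = res.cluster_leaf_sets()[-2:]  # the two children of the root merge
        split = {frozenset(s) for s in top if len(s) == 4}
        assert frozenset([f"g{i}" for i in range(4)]) in split \
            or frozenset([f"g{i}" for i in range(4, 8)]) in split


class TestBootstrapClusters:
    def test_planted_clusters_high_support(self):
        rng = np.random.default_rng(9)
        a = rng.random((4, 50)) + 4.0
        b = rng.random((4, 50))
        ab = pd.DataFrame(np.vstack([a, b]),
                          index=[f"g{i}" for i in range(8)],
                          columns=[f"A{k % 18 + 3}_{k}" for k in range(50)])
        m = MNRAbundanceMatrix(counts=ab.astype(int), abundance=ab,
                               seq_lengths=pd.Series(100, index=ab.index))
        res = bootstrap_clusters(m, replicates=100, seed=0)
        group1 = frozenset([f"g{i}" for i in range(4)])
        group2 = frozenset([f"g{i}" for i in range(4, 8)])
        sup = res.supports
        assert max(sup.get(group1, 0.0), sup.get(group2, 0.0)) >= 0.95
        assert all(0 <= v <= 1 for v in sup.values())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        ab = pd.DataFrame(rng.random((5, 12)),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"C{k+3}" for k in range(12)])
        m = MNRAbundanceMatrix(counts=ab.astype(int), abundance=ab,
                               seq_lengths=pd.Series(100, index=ab.index))
        r1 = bootstrap_clusters(m, replicates=50, seed=7)
        r2 = bootstrap_clusters(m, replicates=50, seed=7)
        assert r1.supports == r2.supports

    def test_newick_export_contains_all_labels(self):
        rng = np.random.default_rng(5)
        ab = pd.DataFrame(rng.random((4, 6)),
                          index=list("wxyz"),
                          columns=[f"G{k+3}" for k in range(6)])
        m = MNRAbundanceMatrix(counts=ab.astype(int), abundance=ab,
                               seq_lengths=pd.Series(100, index=ab.index))
        res = bootstrap_clusters(m, replicates=20, seed=1)
        nwk = res.to_newick(include_support=True)
        assert all(label in nwk for label in "wxyz")
        assert nwk.endswith(";")


class TestSimulatedChloroClades:
    def test_two_clade_tract_seeding_recovered_by_top_split(self):
        """Clade-specific MNR divergence drives the dendrogram's top split."""
        from polyorigin.simulate import ChloroSimConfig, simulate_chloroplast_set

        cfg = ChloroSimConfig(
            genome_length=8000, mnr_seed_count=60, seed=21, indel_rate=0.3,
            tree_newick=("((c1a:0.002,c1b:0.002):0.06,"
                         "(c2a:0.002,c2b:0.002):0.06):0;"),
        )
        seqs, _, _ = simulate_chloroplast_set(cfg)
        m = filter_features(abundance_matrix(sorted(seqs.items())))
        res = cluster_samples(mnr_distance(m))
        sets = res.cluster_leaf_sets()
        assert frozenset(["c1a", "c1b"]) in sets or \
            frozenset(["c2a", "c2b"]) in sets
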