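"""Damage clustering, complexity classification and yield tallies."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chromofiber.clustering import (
    ClusterConfig,
    classify_cluster,
    cluster_breaks,
    clusters_to_frame,
    tally,
    two_ssb_count,
)
from chromofiber.damage import StrandBreak
from chromofiber.errors import InvalidArgumentError

from oracles import brute_damage_counts, component_clusters


def mk(history, strand, bp):
    return StrandBreak(history_id=history, strand=strand, bp_index=bp, edep_eV=20.0)


def random_breaks(rng, n, bp_range=200, histories=3):
    seen = set()
    out = []
    while len(out) < n:
        key = (int(rng.integers(histories)), int(rng.integers(2)), int(rng.integers(bp_range)))
        if key not in seen:
            seen.add(key)
            out.append(mk(*key))
    return out


class TestClusterBreaks:
    def test_within_distance_merges(self):
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 1, 5)], ClusterConfig(10))
        assert len(clusters) == 1 and clusters[0].label == "DSB"

    def test_beyond_distance_splits(self):
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 1, 15)], ClusterConfig(10))
        assert len(clusters) == 2

    def test_empty(self):
        assert cluster_breaks([], ClusterConfig(10)) == []

    def test_histories_never_merge(self):
        clusters = cluster_breaks([mk(0, 0, 0), mk(1, 1, 1)], ClusterConfig(40))
        assert len(clusters) == 2

    def test_chain_connectivity(self):
        """Single linkage: pairwise-distant breaks join through a chain."""
        breaks = [mk(0, 0, 0), mk(0, 0, 9), mk(0, 1, 18)]
        assert len(cluster_breaks(breaks, ClusterConfig(10))) == 1

    def test_agrees_with_component_oracle(self, rng):
        for _ in range(50):
            breaks = random_breaks(rng, int(rng.integers(1, 60)))
            for n_bp in (3, 10, 30):
                got = {frozenset(c.breaks) for c in cluster_breaks(breaks, ClusterConfig(n_bp))}
                assert got == component_clusters(breaks, n_bp)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_cluster_count_non_increasing_in_distance(self, seed):
        rng = np.random.default_rng(seed)
        breaks = random_breaks(rng, 30)
        counts = [len(cluster_breaks(breaks, ClusterConfig(n))) for n in (3, 10, 30, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_distance(self):
        with pytest.raises(InvalidArgumentError):
            ClusterConfig(0)


class TestClassify:
    def test_multiplicity_is_min_strand_count(self):
        breaks = [mk(0, 0, 0), mk(0, 0, 3), mk(0, 0, 6), mk(0, 1, 2), mk(0, 1, 5)]
        label, mult = classify_cluster(breaks, ClusterConfig(10))
        assert (label, mult) == ("DSB++", 2)

    def test_mixed_three_breaks_is_dsb_plus(self):
        label, mult = classify_cluster([mk(0, 0, 0), mk(0, 1, 2), mk(0, 0, 4)], ClusterConfig(10))
        assert (label, mult) == ("DSB+", 1)

    def test_two_ssb_statistic(self):
        """Opposite-strand single-break clusters farther apart than n_bp."""
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 1, 50)], ClusterConfig(10))
        assert [c.label for c in clusters] == ["SSB", "SSB"]
        assert two_ssb_count(clusters) == 1
        # same strand -> no 2SSB
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 0, 50)], ClusterConfig(10))
        assert two_ssb_count(clusters) == 0


class TestTally:
    def test_single_dsb_cluster(self):
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 1, 5)], ClusterConfig(10))
        t = tally(clusters, dose_gy=1.0, genome_bp=1e9)
        assert (t.tsb, t.dsb_count, t.ssb_break_count) == (2, 1, 0)
        assert t.ssb_dsb_ratio == 0.0

    def test_ratio_none_without_dsb(self):
        t = tally(cluster_breaks([mk(0, 0, 0)], ClusterConfig(10)), 1.0, 1e9)
        assert t.ssb_dsb_ratio is None

    def test_dose_linearity(self):
        clusters = cluster_breaks([mk(0, 0, 0), mk(0, 1, 5), mk(1, 0, 9)], ClusterConfig(10))
        t1 = tally(clusters, 1.0, 1e9)
        t2 = tally(clusters, 2.0, 1e9)
        assert t2.ssb_yield == pytest.approx(t1.ssb_yield / 2)
        assert t2.dsb_yield == pytest.approx(t1.dsb_yield / 2)

    def test_rejects_bad_dose(self):
        with pytest.raises(InvalidArgumentError):
            tally([], 0.0, 1e9)

    def test_tsb_identity_random_sets(self, rng):
        """tsb = ssb breaks + 2*dsb on arbitrary break sets."""
        for _ in range(30):
            breaks = random_breaks(rng, int(rng.integers(1, 80)))
            t = tally(cluster_breaks(breaks, ClusterConfig(10)), 1.0, 1e9)
            assert t.tsb == t.ssb_break_count + 2 * t.dsb_count == len(breaks)

    def test_exhaustive_subset_oracle(self):
        """All 2^12 subsets of a fixed 12-break template: tallies equal the
        all-pairs oracle, and damage is monotone under adding breaks."""
        template = [
            mk(0, 0, 0), mk(0, 1, 4), mk(0, 0, 9), mk(0, 1, 30),
            mk(0, 0, 33), mk(0, 1, 61), mk(1, 0, 5), mk(1, 1, 8),
            mk(1, 0, 12), mk(1, 1, 90), mk(1, 0, 93), mk(1, 1, 95),
        ]
        cc = ClusterConfig(10)
        dsb_by_subset = {}
        for mask in range(4096):
            subset = [b for i, b in enumerate(template) if mask >> i & 1]
            clusters = cluster_breaks(subset, cc)
            t = tally(clusters, 1.0, 1e9) if subset else None
            total, dsb, ssb = brute_damage_counts(subset, cc.n_bp)
            if t is not None:
                assert (t.tsb, t.dsb_count, t.ssb_break_count) == (total, dsb, ssb)
            dsb_by_subset[mask] = dsb
        # monotonicity: adding one break never reduces the DSB count
        for mask in range(4096):
            for i in range(12):
                if not mask >> i & 1:
                    assert dsb_by_subset[mask | (1 << i)] >= dsb_by_subset[mask]

    def test_sdd_minimal_writer(self, fiber, tmp_path):
        from chromofiber.clustering import write_sdd_minimal

        clusters = cluster_breaks([mk(0, 0, 10), mk(0, 1, 14), mk(2, 0, 500)], ClusterConfig(10))
        path = tmp_path / "damage.sdd"
        write_sdd_minimal(clusters, fiber, str(path))
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        assert lines[0].split(", ")[4] == "2"  # DSB label code

    def test_cluster_table_columns(self):
        df = clusters_to_frame(cluster_breaks([mk(0, 0, 0), mk(0, 1, 5)], ClusterConfig(10)))
        assert list(df.columns) == ["history_id", "label", "span_min", "span_max", "n_breaks", "dsb_multiplicity"]
        assert df.iloc[0]["label"] == "DSB"
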