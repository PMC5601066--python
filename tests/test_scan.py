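"""Tests of AFD computation, QTL clustering and threshold significance."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolscan import (
    PooledVariant,
    call_qtl,
    compute_afd,
    contrast_table,
    threshold_significance,
)
from poolscan.validation import chisq_homogeneity

MB = 1_000_000


def _v(pos, high, low, chrom="1H"):
    return PooledVariant(chrom, int(pos), "A", "G", 60.0, high, low)


def _afd_at(positions_afd, chrom="1H", depth=1000):
    """AFDRecords with prescribed AFD values: high pool at (1+afd)/2, low at (1-afd)/2."""
    records = []
    for pos, afd in positions_afd:
        rh = (1 + afd) / 2
        rl = (1 - afd) / 2
        records.append(
            _v(pos, (round(depth * rh), depth - round(depth * rh)),
               (round(depth * rl), depth - round(depth * rl)), chrom)
        )
    return compute_afd(records)


# ---------------------------------------------------------------------------
# AFD


def test_afd_arithmetic_from_read_counts():
    rec = compute_afd([_v(100, (150, 50), (25, 75))])[0]
    assert rec.raf_high == pytest.approx(0.75)
    assert rec.raf_low == pytest.approx(0.25)
    assert rec.afd == pytest.approx(0.50)


def test_equal_pools_give_zero_afd():
    rec = compute_afd([_v(100, (120, 80), (120, 80))])[0]
    assert rec.afd == 0.0


@given(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
)
def test_swapping_pools_negates_afd_and_range_holds(a, b, c, d):
    if a + b == 0 or c + d == 0:
        return
    fwd = compute_afd([_v(1, (a, b), (c, d))])[0]
    rev = compute_afd([_v(1, (c, d), (a, b))])[0]
    assert fwd.afd == pytest.approx(-rev.afd)
    assert -1.0 <= fwd.afd <= 1.0


def test_zero_depth_pool_raises():
    with pytest.raises(ValueError, match="zero-depth"):
        compute_afd([_v(100, (0, 0), (10, 10))])


# ---------------------------------------------------------------------------
# QTL clustering


def test_single_passing_marker_yields_degenerate_interval():
    records = _afd_at([(5 * MB, 0.80), (50 * MB, 0.10)])
    calls = call_qtl(records)
    assert len(calls) == 1
    q = calls[0]
    assert q.interval == (5 * MB, 5 * MB)
    assert q.n_markers == 1
    assert q.peak_position == 5 * MB
    assert q.max_afd == pytest.approx(0.80, abs=0.01)


def test_fifteen_megabase_gap_splits_two_qtl():
    records = _afd_at([(1 * MB, 0.8), (5 * MB, 0.8), (20 * MB, 0.8)])
    calls = call_qtl(records)
    assert [(c.interval, c.n_markers) for c in calls] == [
        ((1 * MB, 5 * MB), 2),
        ((20 * MB, 20 * MB), 1),
    ]


def test_intervening_marker_chains_one_qtl():
    records = _afd_at([(1 * MB, 0.8), (5 * MB, 0.8), (12 * MB, 0.8), (20 * MB, 0.8)])
    calls = call_qtl(records)
    assert len(calls) == 1
    assert calls[0].interval == (1 * MB, 20 * MB)
    assert calls[0].n_markers == 4


def test_exact_gap_boundary_separates():
    # "at least 10 Mbp" separation makes QTL independent
    records = _afd_at([(1 * MB, 0.8), (11 * MB, 0.8)])
    assert len(call_qtl(records)) == 2
    records = _afd_at([(1 * MB, 0.8), (11 * MB - 1, 0.8)])
    assert len(call_qtl(records)) == 1


def test_centromeric_span_uses_large_gap():
    centromeres = {"1H": (250 * MB, 350 * MB)}
    # 150 Mbp apart across the centromere: joined under the 400 Mbp gap
    records = _afd_at([(200 * MB, 0.8), (360 * MB, 0.8)])
    assert len(call_qtl(records, centromeres=centromeres)) == 1
    # same separation entirely on one arm: split under the 10 Mbp gap
    records = _afd_at([(400 * MB, 0.8), (560 * MB, 0.8)])
    assert len(call_qtl(records, centromeres=centromeres)) == 2


def test_chromosome_missing_from_centromere_map_uses_small_gap():
    records = _afd_at([(200 * MB, 0.8), (360 * MB, 0.8)], chrom="9H")
    calls = call_qtl(records, centromeres={"1H": (250 * MB, 350 * MB)})
    assert len(calls) == 2


def test_threshold_is_strict():
    records = _afd_at([(1 * MB, 0.75), (2 * MB, 0.76)], depth=400)
    calls = call_qtl(records, threshold=0.75)
    assert len(calls) == 1 and calls[0].n_markers == 1


def test_mixed_signs_cluster_unless_strict_mode():
    records = _afd_at([(1 * MB, 0.9), (3 * MB, -0.9)])
    assert len(call_qtl(records)) == 1
    assert len(call_qtl(records, sign_mode="strict")) == 2


def test_peak_tie_broken_by_smallest_position():
    records = _afd_at([(1 * MB, 0.9), (3 * MB, 0.9)])
    calls = call_qtl(records)
    assert calls[0].peak_position == 1 * MB


def test_call_qtl_is_invariant_to_input_order():
    rng = np.random.default_rng(5)
    pairs = [(int(p), a) for p, a in zip(rng.integers(1, 700 * MB, 30),
                                         rng.uniform(-1, 1, 30))]
    records = _afd_at(pairs)
    base = call_qtl(records, centromeres={"1H": (250 * MB, 350 * MB)})
    shuffled = list(records)
    rng.shuffle(shuffled)
    again = call_qtl(shuffled, centromeres={"1H": (250 * MB, 350 * MB)})
    assert [(c.chromosome, c.interval, c.n_markers, c.peak_position) for c in base] == [
        (c.chromosome, c.interval, c.n_markers, c.peak_position) for c in again
    ]


def _oracle_partitions(positions, gap_for_pair):
    """All contiguous partitions valid under the literal independence rule."""
    k = len(positions)
    valid = []
    for cuts in itertools.product([False, True], repeat=max(k - 1, 0)):
        ok = True
        for i, cut in enumerate(cuts):
            sep = positions[i + 1] - positions[i]
            gap = gap_for_pair(positions[i], positions[i + 1])
            # adjacent passing markers have no intervening passing marker:
            # a cut requires separation >= gap, no cut requires separation < gap
            if cut and sep < gap:
                ok = False
            if not cut and sep >= gap:
                ok = False
        if ok:
            blocks, start = [], 0
            for i, cut in enumerate(cuts):
                if cut:
                    blocks.append(positions[start : i + 1])
                    start = i + 1
            blocks.append(positions[start:])
            valid.append(blocks)
    return valid


@pytest.mark.parametrize("seed", range(6))
def test_clustering_matches_exhaustive_partition_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 15))
    centromere = (250 * MB, 350 * MB)

    def gap_for_pair(lo, hi):
        return 400 * MB if (lo <= centromere[1] and hi >= centromere[0]) else 10 * MB

    positions = sorted(int(p) for p in rng.choice(600 * MB, size=n, replace=False))
    # every marker passes the threshold
    records = _afd_at([(p, float(rng.choice([0.8, 0.9, -0.85]))) for p in positions])
    partitions = _oracle_partitions(positions, gap_for_pair)
    assert len(partitions) == 1, "independence rule must define a unique partition"
    calls = call_qtl(records, centromeres={"1H": centromere})
    assert [list(range_) for range_ in partitions[0]] == [
        [m for m in positions if c.interval[0] <= m <= c.interval[1]] for c in calls
    ]
    assert [c.n_markers for c in calls] == [len(b) for b in partitions[0]]


def test_every_passing_marker_in_exactly_one_call():
    rng = np.random.default_rng(12)
    pairs = [(int(p), float(a)) for p, a in zip(
        rng.choice(700 * MB, 40, replace=False), rng.uniform(-1, 1, 40))]
    records = _afd_at(pairs)
    calls = call_qtl(records, centromeres={"1H": (250 * MB, 350 * MB)})
    passing = [r for r in records if abs(r.afd) > 0.75]
    for r in passing:
        covering = [
            c for c in calls
            if c.chromosome == r.variant.chromosome
            and c.interval[0] <= r.variant.position <= c.interval[1]
        ]
        assert len(covering) == 1
    assert sum(c.n_markers for c in calls) == len(passing)
    for c in calls:
        assert abs(c.max_afd) > 0.75
        members = [r for r in passing if c.interval[0] <= r.variant.position <= c.interval[1]]
        assert abs(c.max_afd) == pytest.approx(max(abs(m.afd) for m in members))


# ---------------------------------------------------------------------------
# threshold significance


def test_afd_075_pools_of_12_implies_minus_log10p_3_8():
    assert round(threshold_significance(0.75, 12), 1) == 3.8


def test_contrast_table_and_chi2_for_default_threshold():
    table = contrast_table(0.75, 12)
    assert table.tolist() == [[12, 0], [3, 9]]
    assert chisq_homogeneity(table).chi2 == pytest.approx(14.4)


def test_complete_separation_table_gives_chi2_24():
    table = contrast_table(1.0, 12)
    assert table.tolist() == [[12, 0], [0, 12]]
    assert chisq_homogeneity(table).chi2 == pytest.approx(24.0)


def test_invalid_threshold_rejected():
    with pytest.raises(ValueError):
        threshold_significance(0.0, 12)
    with pytest.raises(ValueError):
        threshold_significance(1.5, 12)
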