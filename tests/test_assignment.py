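"""Assignment quality Q and the iterative min-Q reassignment."""

import numpy as np
import pytest

from dynreconf import (
    CanonicalPartition,
    assignment_quality,
    best_target_network,
    dynamic_assignment,
    iterative_reassignment,
)
from dynreconf.assignment import all_assignment_quality
from dynreconf.datatypes import ConnectivityStack, DynreconfError

from conftest import block_connectivity, block_timeseries, random_connectivity


# ---------------------------------------------------------------- oracles
def q_oracle(conn, codes, region):
    """Double-loop Q: mean within-network minus mean elsewhere over their sum."""
    n = conn.shape[0]
    within, between = [], []
    for j in range(n):
        if j == region:
            continue
        (within if codes[j] == codes[region] else between).append(conn[region, j])
    cw = float(np.mean(within)) if within else 0.0
    cb = float(np.mean(between)) if between else 0.0
    return (cw - cb) / (cw + cb) if (cw + cb) > 0 else 0.0


def best_target_oracle(conn, codes, region, k):
    """Enumerate candidate networks; mean connectivity excluding self; ties ->
    current network, then lowest index."""
    best, best_val = None, -np.inf
    for h in range(k):
        members = [j for j in range(len(codes)) if codes[j] == h and j != region]
        if not members:
            continue
        val = float(np.mean([conn[region, j] for j in members]))
        if val > best_val:
            best, best_val = h, val
    if best is not None:
        g = codes[region]
        members = [j for j in range(len(codes)) if codes[j] == g and j != region]
        if members and float(np.mean([conn[region, j] for j in members])) == best_val:
            return g
    return best


def reassign_reference(conn, codes, k, max_iterations=10_000):
    """Pure-Python trajectory oracle for the full loop."""
    conn = conn.copy()
    np.fill_diagonal(conn, 0.0)
    codes = list(codes)
    prev = -1
    for _ in range(max_iterations):
        qs = [q_oracle(conn, codes, i) for i in range(len(codes))]
        sel = int(np.argmin(qs))
        if sel == prev:
            return np.array(codes), True
        tgt = best_target_oracle(conn, codes, sel, k)
        if tgt is not None:
            codes[sel] = tgt
        prev = sel
    return np.array(codes), False


# ---------------------------------------------------------------- Q itself
def test_q_direct_arithmetic():
    # region 0: one same-network neighbour at 0.8, two others at 0.2
    conn = np.array(
        [
            [np.nan, 0.8, 0.2, 0.2],
            [0.8, np.nan, 0.3, 0.3],
            [0.2, 0.3, np.nan, 0.5],
            [0.2, 0.3, 0.5, np.nan],
        ]
    )
    q = assignment_quality(conn, [0, 0, 1, 1], region=0)
    assert q.c_within == pytest.approx(0.8)
    assert q.c_between == pytest.approx(0.2)
    assert q.q_value == pytest.approx(0.6)


def test_q_zero_when_within_equals_between():
    conn = np.full((4, 4), 0.4)
    np.fill_diagonal(conn, np.nan)
    assert assignment_quality(conn, [0, 0, 1, 1], 0).q_value == pytest.approx(0.0)


def test_singleton_network_gets_most_negative_q():
    conn = np.full((5, 5), 0.4)
    np.fill_diagonal(conn, np.nan)
    q = assignment_quality(conn, [0, 1, 1, 1, 1], 0)
    assert q.c_within == 0.0
    assert q.q_value == pytest.approx(-1.0)


def test_q_matches_double_loop_oracle(rng):
    for _ in range(50):
        conn = random_connectivity(rng, 8)
        codes = rng.integers(0, 3, 8)
        qs = all_assignment_quality(conn, codes, 3)
        for i in range(8):
            assert qs[i] == pytest.approx(q_oracle(np.nan_to_num(conn), codes, i), abs=1e-12)
            assert assignment_quality(conn, codes, i, 3).q_value == pytest.approx(
                qs[i], abs=1e-12
            )


# ------------------------------------------------------------ best target
def test_best_target_dominance_and_tie_rules(rng):
    conn = block_connectivity([3, 3], within=0.9, between=0.1)
    # region 3 currently in block 1 but all its strong edges are in block 1:
    # move region 3's labels so it's in block 0 -> should return block 1
    codes = np.array([0, 0, 0, 0, 1, 1])
    assert best_target_network(conn, codes, 3) == 1
    # exact tie: uniform matrix -> current network retained
    uni = np.full((6, 6), 0.5)
    np.fill_diagonal(uni, np.nan)
    assert best_target_network(uni, np.array([0, 0, 0, 1, 1, 1]), 2) == 0
    for _ in range(30):
        c = random_connectivity(rng, 6)
        codes = rng.integers(0, 3, 6)
        assert best_target_network(c, codes, 2, 3) == best_target_oracle(
            np.nan_to_num(c), codes, 2, 3
        )


# -------------------------------------------------------- iterative loop
def test_mislabeled_region_is_corrected():
    conn = block_connectivity([3, 3], within=0.9, between=0.1)
    init = np.array([0, 0, 1, 1, 1, 1])  # region 2 mislabeled into block B
    final, log = iterative_reassignment(conn, init, n_networks=2)
    assert list(final) == [0, 0, 0, 1, 1, 1]
    assert log["converged"]


def test_perfect_partition_is_fixed_point():
    conn = block_connectivity([3, 3], within=0.9, between=0.1)
    init = np.array([0, 0, 0, 1, 1, 1])
    final, log = iterative_reassignment(conn, init, n_networks=2)
    assert np.array_equal(final, init)
    assert log["converged"] and log["iterations"] <= 2 and log["moves"] == 0


def test_uniform_matrix_keeps_labels():
    conn = np.full((6, 6), 0.5)
    np.fill_diagonal(conn, np.nan)
    init = np.array([0, 0, 1, 1, 2, 2])
    final, log = iterative_reassignment(conn, init, n_networks=3)
    assert np.array_equal(final, init)
    assert log["converged"]


def test_kernel_matches_pure_python_reference(rng):
    """Compiled loop vs the slow trajectory oracle on random matrices."""
    for _ in range(25):
        conn = random_connectivity(rng, 10)
        init = rng.integers(0, 3, 10)
        got, log = iterative_reassignment(conn, init.copy(), n_networks=3)
        want, conv = reassign_reference(conn, init, 3)
        assert np.array_equal(got, want)
        assert log["converged"] == conv


def test_result_invariant_to_region_permutation(rng):
    conn = block_connectivity([4, 4, 4], within=0.8, between=0.1, jitter=0.02, rng=rng)
    init = np.repeat([0, 1, 2], 4)
    init[3] = 1  # one mislabeled region
    final, _ = iterative_reassignment(conn, init, n_networks=3)
    perm = rng.permutation(12)
    conn_p = conn[np.ix_(perm, perm)]
    final_p, _ = iterative_reassignment(conn_p, init[perm], n_networks=3)
    assert np.array_equal(final_p, final[perm])


def test_recovery_with_clean_margin(rng):
    """Block-diagonal with margin >= 0.5 and one mislabeled region per block."""
    for seed in range(20):
        r = np.random.default_rng(seed)
        conn = block_connectivity([5, 5, 5], within=0.8, between=0.1, jitter=0.03, rng=r)
        truth = np.repeat([0, 1, 2], 5)
        init = truth.copy()
        init[0], init[5], init[10] = 1, 2, 0  # one wrong label per block
        final, log = iterative_reassignment(conn, init, n_networks=3)
        assert np.array_equal(final, truth)
        assert log["converged"]


# ------------------------------------------------------- stack-level API
def test_dynamic_assignment_identical_windows(small_partition, rng):
    conn = block_connectivity([4, 4, 4], within=0.8, between=0.1, jitter=0.02, rng=rng)
    stack = ConnectivityStack(
        matrices=np.repeat(conn[None], 5, axis=0),
        window_starts=np.arange(5),
        window_length_volumes=10,
        weights_profile=np.ones(10),
        region_ids=tuple(small_partition.labels),
    )
    am = dynamic_assignment(stack, small_partition)
    for k in range(1, 5):
        assert np.array_equal(am.codes[:, k], am.codes[:, 0])
    assert all(entry["converged"] for entry in am.iteration_log)


def test_planted_move_detected_at_its_transition(small_partition, rng):
    """Non-overlapping windows; region 0 moves A->B at transition 2 and only there."""
    w = 40
    codes_static = np.repeat([0, 1, 2], 4)
    codes = np.repeat(codes_static[:, None], 6 * w, axis=1)
    codes[0, 3 * w :] = 1  # move takes effect at the start of window 3
    ts = block_timeseries(rng, codes, rho_w=0.95, rho_b=0.02)
    from dynreconf import WindowSpec, build_stack

    stack = build_stack(ts, WindowSpec(length_seconds=w, step_seconds=w))
    am = dynamic_assignment(stack, small_partition)
    row = am.codes[0]
    assert list(row[:3]) == [0, 0, 0]
    assert list(row[3:]) == [1, 1, 1]
    others = am.codes[1:]
    assert np.array_equal(others, np.repeat(codes_static[1:][:, None], 6, axis=1))


def test_empty_stack_rejected(small_partition):
    stack = ConnectivityStack(
        matrices=np.empty((0, 12, 12)),
        window_starts=np.empty(0, dtype=int),
        window_length_volumes=10,
        weights_profile=np.ones(10),
        region_ids=tuple(small_partition.labels),
    )
    with pytest.raises(DynreconfError):
        dynamic_assignment(stack, small_partition)
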