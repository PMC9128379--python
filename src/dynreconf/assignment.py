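"""Iterative subnetwork reassignment by assignment quality Q.

Each window's connectivity matrix starts from the canonical 7-network
partition.  The assignment quality of region *i* is

    Q_i = (C_within - C_between) / (C_within + C_between)

where C_within is the mean connectivity of *i* to the other members of its
assigned subnetwork and C_between the mean connectivity to all remaining
regions (the diagonal never enters either mean).  Each iteration selects the
region with the worst Q and reassigns it to the subnetwork it connects to most
strongly; the loop stops when the same region is selected in two successive
iterations, i.e. no further improvement is possible.

Tie-breaking is fixed for bit-reproducibility: argmin Q resolves to the lowest
region index; the best target network prefers the region's current network,
then the lowest network index.  Edge cases: a region alone in its subnetwork
has C_within = 0 (hence strongly negative Q, prioritising reassignment);
emptied subnetworks remain in the label set but are not reassignment targets
while empty; an all-zero connectivity row yields Q = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AssignmentMatrix,
    CanonicalPartition,
    ConnectivityStack,
    DynreconfError,
)

#: Hard iteration cap multiplier: the stopping rule alone does not provably
#: terminate, so each window runs at most ITERATION_CAP_FACTOR * n_regions
#: iterations and logs non-convergence.
ITERATION_CAP_FACTOR = 100


@dataclass
class AssignmentQuality:
    """Q for one region under one partition, with its two components."""

    q_value: float
    c_within: float
    c_between: float


def _clean_conn(conn: np.ndarray) -> np.ndarray:
    """Validate a connectivity matrix and return a copy with a zero diagonal.

    The diagonal is excluded by contract (NaN in stacks); zeroing it lets
    row sums skip it without masking.
    """
    conn = np.array(conn, dtype=float)
    if conn.ndim != 2 or conn.shape[0] != conn.shape[1]:
        raise DynreconfError("connectivity matrix must be square")
    np.fill_diagonal(conn, 0.0)
    if not np.all(np.isfinite(conn)):
        raise DynreconfError("connectivity matrix has non-finite off-diagonal entries")
    if not np.allclose(conn, conn.T, atol=1e-12, rtol=0.0):
        raise DynreconfError("connectivity matrix is not symmetric")
    return conn


def _network_sums(conn0: np.ndarray, codes: np.ndarray, n_networks: int) -> np.ndarray:
    """S[i, g] = sum of conn0[i, j] over regions j assigned to network g."""
    n = conn0.shape[0]
    z = np.zeros((n, n_networks))
    z[np.arange(n), codes] = 1.0
    return conn0 @ z


def all_assignment_quality(
    conn: np.ndarray, codes: np.ndarray, n_networks: int
) -> np.ndarray:
    """Vectorised Q for every region under ``codes`` (fresh computation)."""
    conn0 = _clean_conn(conn)
    codes = np.asarray(codes, dtype=np.int64)
    n = conn0.shape[0]
    counts = np.bincount(codes, minlength=n_networks)
    s = _network_sums(conn0, codes, n_networks)
    own = s[np.arange(n), codes]
    n_same = counts[codes] - 1  # other members of own network
    cw = np.where(n_same > 0, own / np.maximum(n_same, 1), 0.0)
    n_other = n - counts[codes]
    rowsum = conn0.sum(axis=1)
    cb = np.where(n_other > 0, (rowsum - own) / np.maximum(n_other, 1), 0.0)
    denom = cw + cb
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(denom > 0, (cw - cb) / np.where(denom > 0, denom, 1.0), 0.0)
    return q


def assignment_quality(
    conn: np.ndarray, codes: np.ndarray, region: int, n_networks: int | None = None
) -> AssignmentQuality:
    """Assignment quality of one region.

    Parameters
    ----------
    conn : square symmetric matrix (diagonal ignored)
    codes : integer network code per region
    region : index of the region to score
    n_networks : total number of networks; defaults to ``max(codes) + 1``
    """
    conn0 = _clean_conn(conn)
    codes = np.asarray(codes, dtype=np.int64)
    if n_networks is None:
        n_networks = int(codes.max()) + 1
    n = conn0.shape[0]
    if not 0 <= region < n:
        raise DynreconfError(f"region {region} outside 0..{n - 1}")
    g = codes[region]
    same = (codes == g) & (np.arange(n) != region)
    other = codes != g
    cw = float(conn0[region, same].mean()) if same.any() else 0.0
    cb = float(conn0[region, other].mean()) if other.any() else 0.0
    q = (cw - cb) / (cw + cb) if (cw + cb) > 0 else 0.0
    return AssignmentQuality(q_value=q, c_within=cw, c_between=cb)


def best_target_network(
    conn: np.ndarray, codes: np.ndarray, region: int, n_networks: int | None = None
) -> int:
    """Network with the highest mean connectivity to ``region`` (self excluded).

    Candidates are the currently non-empty networks (membership counted
    without the region itself), including its own; ties prefer the current
    network, then the lowest network index.
    """
    conn0 = _clean_conn(conn)
    codes = np.asarray(codes, dtype=np.int64)
    if n_networks is None:
        n_networks = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_networks)
    g = int(codes[region])
    s = _network_sums(conn0, codes, n_networks)[region]
    denom = counts.astype(float)
    denom[g] -= 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), -np.inf)
    if not np.any(np.isfinite(means)):
        raise DynreconfError("no non-empty candidate network")
    best = int(np.argmax(means))  # argmax -> lowest index on exact ties
    if means[g] == means[best]:
        return g
    return best


@njit(cache=True)
def _reassign_kernel(conn0, codes, n_networks, max_iterations):  # pragma: no cover
    """Min-Q reassignment loop with incrementally maintained network sums.

    Results are identical to recomputing Q from scratch each iteration
    (up to float associativity); compiled for speed.
    Returns (codes, iterations, moves, converged).
    """
    n = conn0.shape[0]
    s = np.zeros((n, n_networks))
    counts = np.zeros(n_networks, dtype=np.int64)
    rowsum = np.zeros(n)
    for i in range(n):
        counts[codes[i]] += 1
        acc = 0.0
        for j in range(n):
            s[i, codes[j]] += conn0[i, j]
            acc += conn0[i, j]
        rowsum[i] = acc
    prev = -1
    moves = 0
    iterations = 0
    converged = False
    while iterations < max_iterations:
        iterations += 1
        worst_q = np.inf
        sel = -1
        for i in range(n):
            g = codes[i]
            cw = s[i, g] / (counts[g] - 1) if counts[g] > 1 else 0.0
            n_other = n - counts[g]
            cb = (rowsum[i] - s[i, g]) / n_other if n_other > 0 else 0.0
            denom = cw + cb
            q = (cw - cb) / denom if denom > 0 else 0.0
            if q < worst_q:
                worst_q = q
                sel = i
        if sel == prev:
            converged = True
            break
        g = codes[sel]
        best_m = -np.inf
        tgt = -1
        for h in range(n_networks):
            d = counts[h] - (1 if h == g else 0)
            if d <= 0:
                continue
            m = s[sel, h] / d
            if m > best_m:
                best_m = m
                tgt = h
        cur_d = counts[g] - 1
        if cur_d > 0 and s[sel, g] / cur_d == best_m:
            tgt = g  # tie prefers the current network
        if tgt >= 0 and tgt != g:
            codes[sel] = tgt
            counts[g] -= 1
            counts[tgt] += 1
            for i in range(n):
                s[i, g] -= conn0[i, sel]
                s[i, tgt] += conn0[i, sel]
            moves += 1
        prev = sel
    return codes, iterations, moves, converged


def iterative_reassignment(
    conn: np.ndarray,
    initial_codes: np.ndarray,
    n_networks: int | None = None,
    max_iterations: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the min-Q reassignment loop on one connectivity matrix.

    Returns the final integer codes and a log dict with keys
    ``iterations``, ``moves``, ``converged``.  Hitting the hard iteration
    cap is logged (``converged`` False), never raised.
    """
    conn0 = np.ascontiguousarray(_clean_conn(conn))
    codes = np.asarray(initial_codes, dtype=np.int64).copy()
    if codes.shape[0] != conn0.shape[0]:
        raise DynreconfError("one initial code per region required")
    if n_networks is None:
        n_networks = int(codes.max()) + 1
    if max_iterations is None:
        max_iterations = ITERATION_CAP_FACTOR * conn0.shape[0]
    codes, iterations, moves, converged = _reassign_kernel(
        conn0, codes, n_networks, max_iterations
    )
    return codes, {
        "iterations": int(iterations),
        "moves": int(moves),
        "converged": bool(converged),
    }


def dynamic_assignment(
    stack: ConnectivityStack,
    canonical: CanonicalPartition,
    warm_start: bool = False,
    max_iterations: int | None = None,
) -> AssignmentMatrix:
    """Solve every window of a stack, producing the region x window label matrix.

    By default each window initialises from the canonical partition and is
    solved independently (the result does not depend on processing order).
    ``warm_start=True`` instead initialises each window from the previous
    window's solution.
    """
    if stack.n_windows == 0:
        raise DynreconfError("empty connectivity stack")
    region_ids = stack.region_ids or tuple(f"r{i:03d}" for i in range(stack.n_regions))
    init = canonical.codes_for(region_ids)
    out = np.empty((stack.n_regions, stack.n_windows), dtype=np.int64)
    log: list[dict] = []
    current = init
    for k in range(stack.n_windows):
        start_codes = current if warm_start else init
        codes, entry = iterative_reassignment(
            stack.matrices[k], start_codes, canonical.n_networks, max_iterations
        )
        out[:, k] = codes
        entry["window"] = k
        log.append(entry)
        current = codes
    return AssignmentMatrix(
        codes=out,
        network_names=canonical.network_names,
        region_ids=tuple(region_ids),
        initial_partition=canonical,
        iteration_log=log,
    )


class DynamicSubnetworkAssignment(TransformerMixin, BaseEstimator):
    """Transformer: :class:`ConnectivityStack` -> :class:`AssignmentMatrix`."""

    def __init__(
        self,
        canonical: CanonicalPartition | None = None,
        warm_start: bool = False,
        max_iterations: int | None = None,
    ):
        self.canonical = canonical
        self.warm_start = warm_start
        self.max_iterations = max_iterations

    def fit(self, X: ConnectivityStack | None = None, y=None):
        if self.canonical is None:
            raise DynreconfError("a CanonicalPartition is required")
        return self

    def transform(self, X: ConnectivityStack) -> AssignmentMatrix:
        self.fit(X)
        return dynamic_assignment(
            X, self.canonical, warm_start=self.warm_start, max_iterations=self.max_iterations
        )
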