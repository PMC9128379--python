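"""Node reconfiguration metrics and their aggregation.

From a region x window label matrix, four per-node summaries of switching
behaviour are computed:

* **promiscuity** — distinct subnetworks visited / total subnetworks;
* **flexibility** — label changes / possible changes (W - 1 transitions);
* **cohesion** — mutual switches / (W - 1): switches made *together with*
  at least one other region into the same target subnetwork at the same
  transition;
* **disjointedness** — independent switches / (W - 1): switches made alone.

Every switch is classified exactly once, so flexibility = cohesion +
disjointedness holds exactly for every node.  Node values are averaged over
all regions canonically assigned to the same subnetwork (seven values per
metric per subject), z-scored against the healthy-control distribution per
time-point, and the seven network z-scores are averaged into one global value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AssignmentMatrix, CanonicalPartition, DynreconfError

METRICS = ("promiscuity", "flexibility", "cohesion", "disjointedness")


class DegenerateReferenceError(DynreconfError):
    """The HC reference distribution has zero spread, so z-scores are undefined."""


@dataclass
class NodeReconfigMetrics:
    """Reconfiguration summary for one region.

    ``cohesion``/``disjointedness`` are ``None`` when the row was scored in
    isolation (mutuality is defined relative to the other regions' switches).
    """

    promiscuity: float
    flexibility: float
    cohesion: float | None
    disjointedness: float | None
    n_switches: int
    n_distinct: int


def _as_codes(assignments: AssignmentMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(assignments, AssignmentMatrix):
        return assignments.codes, len(assignments.network_names)
    codes = np.asarray(assignments)
    return codes, int(codes.max()) + 1


def node_metrics(
    row: np.ndarray, n_networks: int, mutual_count: int | None = None
) -> NodeReconfigMetrics:
    """Metrics for a single region's window-label sequence.

    ``mutual_count`` (from :func:`classify_switches`) supplies the number of
    the region's switches that were mutual; without it only promiscuity and
    flexibility are defined.
    """
    row = np.asarray(row)
    w = row.shape[0]
    if w < 2:
        raise DynreconfError(f"metrics undefined for {w} window(s); need >= 2")
    switches = int(np.sum(row[1:] != row[:-1]))
    distinct = len(np.unique(row))
    if distinct > n_networks:
        raise DynreconfError("more distinct labels than networks")
    cohesion = disjointedness = None
    if mutual_count is not None:
        if not 0 <= mutual_count <= switches:
            raise DynreconfError("mutual_count outside [0, n_switches]")
        cohesion = mutual_count / (w - 1)
        disjointedness = (switches - mutual_count) / (w - 1)
    return NodeReconfigMetrics(
        promiscuity=distinct / n_networks,
        flexibility=switches / (w - 1),
        cohesion=cohesion,
        disjointedness=disjointedness,
        n_switches=switches,
        n_distinct=distinct,
    )


def classify_switches(
    assignments: AssignmentMatrix | np.ndarray,
    same_source: bool = False,
    pairwise: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Split every region's switches into mutual and independent counts.

    A switch of region *r* at transition *t* into target network *g* is
    *mutual* iff at least one other region also switches at *t* into *g*
    (with ``same_source=True``, additionally from the same source network);
    otherwise it is *independent*.  Returns ``(mutual, independent,
    pairwise_matrix)`` with the region x region mutual co-switch count matrix
    when ``pairwise`` is requested, else ``None``.
    """
    codes, _ = _as_codes(assignments)
    n, w = codes.shape
    if w < 2:
        raise DynreconfError("switch classification needs >= 2 windows")
    mutual = np.zeros(n, dtype=np.int64)
    independent = np.zeros(n, dtype=np.int64)
    pair = np.zeros((n, n), dtype=np.int64) if pairwise else None
    for t in range(w - 1):
        moved = np.flatnonzero(codes[:, t + 1] != codes[:, t])
        if moved.size == 0:
            continue
        tgt = codes[moved, t + 1]
        src = codes[moved, t]
        key = src * 10_000 + tgt if same_source else tgt
        uniq, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
        is_mutual = counts[inverse] >= 2
        mutual[moved[is_mutual]] += 1
        independent[moved[~is_mutual]] += 1
        if pair is not None:
            for k in np.flatnonzero(counts >= 2):
                group = moved[inverse == k]
                for a_idx, a in enumerate(group):
                    for b in group[a_idx + 1 :]:
                        pair[a, b] += 1
                        pair[b, a] += 1
    return mutual, independent, pair


def metrics_frame(
    assignments: AssignmentMatrix | np.ndarray,
    n_networks: int | None = None,
    same_source: bool = False,
) -> pd.DataFrame:
    """All four node metrics for every region, as a DataFrame.

    Index: region position (or region id when an :class:`AssignmentMatrix`
    is given); columns: the four metrics plus raw switch counts.
    """
    codes, k = _as_codes(assignments)
    if n_networks is not None:
        k = n_networks
    n, w = codes.shape
    if w < 2:
        raise DynreconfError("metrics need >= 2 windows")
    mutual, independent, _ = classify_switches(codes, same_source=same_source)
    switches = (codes[:, 1:] != codes[:, :-1]).sum(axis=1)
    distinct = np.array([len(np.unique(codes[i])) for i in range(n)])
    index: pd.Index
    if isinstance(assignments, AssignmentMatrix):
        index = pd.Index(assignments.region_ids, name="region")
    else:
        index = pd.RangeIndex(n, name="region")
    cohesion = mutual / (w - 1)
    disjointedness = independent / (w - 1)
    # flexibility is built from its decomposition so that
    # flexibility == cohesion + disjointedness holds bit-exactly
    # (within 1 ulp of switches/(w-1), and equal whenever the sum is exact)
    return pd.DataFrame(
        {
            "promiscuity": distinct / k,
            "flexibility": cohesion + disjointedness,
            "cohesion": cohesion,
            "disjointedness": disjointedness,
            "n_switches": switches,
            "n_mutual": mutual,
            "n_independent": independent,
            "n_distinct": distinct,
        },
        index=index,
    )


def aggregate_subject(
    node_df: pd.DataFrame, canonical: CanonicalPartition
) -> pd.DataFrame:
    """Average node metrics over the regions canonically assigned to each subnetwork.

    Grouping always uses the *initial* (canonical) labels, not the dynamic
    ones.  Returns a network x metric DataFrame (7 rows, 4 columns).
    """
    missing = [r for r in node_df.index if r not in canonical.labels]
    if missing:
        raise DynreconfError(f"regions without canonical label: {missing[:5]}")
    groups = pd.Series({r: canonical.labels[r] for r in node_df.index}, name="network")
    counts = groups.value_counts()
    empty = [n for n in canonical.network_names if counts.get(n, 0) == 0]
    if empty:
        raise DynreconfError(f"canonical networks with zero regions: {empty}")
    means = node_df[list(METRICS)].groupby(groups).mean()
    return means.reindex(list(canonical.network_names))


def reference_to_controls(
    raw: pd.DataFrame, hc_subject_ids, ddof: int = 1
) -> pd.DataFrame:
    """HC-referenced z-scores per network/metric/time-point, plus a global value.

    ``raw`` is long format with columns ``subject_id, timepoint, metric,
    network, value``.  For each (timepoint, metric, network) cell the healthy
    controls' mean and sample SD (``ddof=1``) define the reference:
    ``z = (value - HC mean) / HC SD`` — this per-time-point referencing also
    absorbs scanner/session effects.  Rows with ``network == "global"`` are
    appended: the mean of each subject's seven network z-scores (and of the
    raw network values, for convenience).
    """
    required = {"subject_id", "timepoint", "metric", "network", "value"}
    if not required.issubset(raw.columns):
        raise DynreconfError(f"raw metric table needs columns {sorted(required)}")
    hc = set(hc_subject_ids)
    out = raw.copy()
    out["z"] = np.nan
    for (tp, metric, network), idx in out.groupby(
        ["timepoint", "metric", "network"]
    ).groups.items():
        block = out.loc[idx]
        ref = block.loc[block["subject_id"].isin(hc), "value"]
        if len(ref) < 2:
            raise DegenerateReferenceError(
                f"need >= 2 HC subjects for {metric}/{network} at {tp}, got {len(ref)}"
            )
        sd = ref.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateReferenceError(
                f"HC SD is zero for {metric}/{network} at {tp}"
            )
        out.loc[idx, "z"] = (block["value"] - ref.mean()) / sd
    glob = (
        out.groupby(["subject_id", "timepoint", "metric"], as_index=False)
        .agg(value=("value", "mean"), z=("z", "mean"))
        .assign(network="global")
    )
    return pd.concat([out, glob], ignore_index=True)[
        ["subject_id", "timepoint", "metric", "network", "value", "z"]
    ]
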