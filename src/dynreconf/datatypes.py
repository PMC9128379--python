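"""Core containers for dynamic functional-network reconfiguration analysis.

A subject's resting-state scan enters the pipeline as a region x volume BOLD
matrix (:class:`TimeSeriesMatrix`).  Regions carry a canonical assignment to
one of seven literature resting-state subnetworks (:class:`CanonicalPartition`);
the windowed connectivity stage produces a :class:`ConnectivityStack`, and the
per-window iterative reassignment produces an :class:`AssignmentMatrix` — the
substrate of every reconfiguration metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The seven canonical resting-state subnetworks used throughout:
#: default-mode, fronto-parietal, dorsal attention, ventral attention,
#: visual, sensorimotor, and deep grey matter.
DEFAULT_NETWORKS: tuple[str, ...] = (
    "DMN", "FPN", "DAN", "VAN", "visual", "SMN", "DGM",
)


class DynreconfError(ValueError):
    """Base class for domain errors raised by this package."""


class DegenerateWindowError(DynreconfError):
    """A region has zero variance inside a window, so its correlations are undefined."""


class WindowSizingError(DynreconfError):
    """The requested window does not fit in the time series."""


@dataclass
class TimeSeriesMatrix:
    """One subject/time-point's region x volume signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_volumes)
        Real-valued BOLD signal, one row per region. Units are arbitrary:
        all downstream analysis is correlation-based.
    tr_seconds : float
        Repetition time in seconds (sampling interval of the columns).
    region_ids : sequence of str, optional
        Ordered region labels; defaults to ``r000, r001, ...``.
    """

    values: np.ndarray
    tr_seconds: float
    region_ids: tuple[str, ...] = ()
    subject_id: str = ""
    timepoint_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DynreconfError(
                f"time series must be 2-D (regions x volumes), got shape {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise DynreconfError("need at least 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise DynreconfError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise DynreconfError("tr_seconds must be positive")
        if not self.region_ids:
            self.region_ids = tuple(f"r{i:03d}" for i in range(self.values.shape[0]))
        self.region_ids = tuple(self.region_ids)
        if len(self.region_ids) != self.values.shape[0]:
            raise DynreconfError(
                f"{len(self.region_ids)} region ids for {self.values.shape[0]} rows"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class CanonicalPartition:
    """Region -> subnetwork labels from the literature parcellation.

    Also serves as the initial assignment of every window in the iterative
    reassignment.  ``network_names`` fixes the network index order used by
    all tie-breaking rules.
    """

    labels: dict[str, str]
    network_names: tuple[str, ...] = DEFAULT_NETWORKS

    def __post_init__(self) -> None:
        self.network_names = tuple(self.network_names)
        unknown = {v for v in self.labels.values()} - set(self.network_names)
        if unknown:
            raise DynreconfError(f"labels reference unknown networks: {sorted(unknown)}")
        present = {v for v in self.labels.values()}
        empty = [n for n in self.network_names if n not in present]
        if empty:
            raise DynreconfError(f"networks empty at initialization: {empty}")

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def codes_for(self, region_ids: Sequence[str]) -> np.ndarray:
        """Integer network codes (index into ``network_names``) for the given regions."""
        idx = {n: i for i, n in enumerate(self.network_names)}
        try:
            return np.array([idx[self.labels[r]] for r in region_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DynreconfError(f"region without canonical label: {exc}") from exc

    @classmethod
    def from_codes(
        cls,
        codes: Sequence[int],
        region_ids: Sequence[str],
        network_names: Sequence[str] = DEFAULT_NETWORKS,
    ) -> "CanonicalPartition":
        names = tuple(network_names)
        return cls(
            labels={r: names[c] for r, c in zip(region_ids, codes)},
            network_names=names,
        )


@dataclass
class ConnectivityStack:
    """Per-window absolute Fisher-z connectivity matrices.

    ``matrices`` has shape (n_windows, n_regions, n_regions); each slice is
    symmetric with NaN on the diagonal — the diagonal is *excluded*, never a
    valid connectivity value, and must not enter any average.
    """

    matrices: np.ndarray
    window_starts: np.ndarray
    window_length_volumes: int
    weights_profile: np.ndarray
    region_ids: tuple[str, ...] = ()
    tr_seconds: float = float("nan")

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclass
class AssignmentMatrix:
    """Region x window subnetwork labels from the iterative reassignment.

    ``codes`` stores integer network indices; :attr:`names` renders them as
    network-name strings.  ``iteration_log`` holds one record per window:
    iterations run, regions moved, and whether the stopping rule fired
    before the hard cap.
    """

    codes: np.ndarray
    network_names: tuple[str, ...]
    region_ids: tuple[str, ...]
    initial_partition: CanonicalPartition | None = None
    iteration_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise DynreconfError("assignment codes must be region x window")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= len(self.network_names):
            raise DynreconfError("assignment code outside network_names range")

    @property
    def n_regions(self) -> int:
        return self.codes.shape[0]

    @property
    def n_windows(self) -> int:
        return self.codes.shape[1]

    @property
    def names(self) -> np.ndarray:
        """Labels as an array of network-name strings."""
        return np.asarray(self.network_names, dtype=object)[self.codes]
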