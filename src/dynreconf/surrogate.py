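"""Phase-randomization surrogate time series and the dynamic null ensemble.

A surrogate series keeps each region's Fourier amplitude spectrum but draws
new phases, destroying genuine time-resolved switching while preserving the
power spectrum.  With one shared phase vector across regions
(``common_phase``, the default) all cross-spectra — and hence the full-series
static correlation structure — are preserved exactly, so the null isolates
*dynamic* reconfiguration from static connectivity differences.  With
independent phases per region the surrogate is a pure-noise null that also
destroys static coupling.

The ensemble runs the complete windows -> assignment -> metrics pipeline on
each surrogate and averages the per-subnetwork metrics over runs, yielding a
per-subject null level for each reconfiguration metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import dynamic_assignment
from .datatypes import CanonicalPartition, DynreconfError, TimeSeriesMatrix
from .metrics import METRICS, aggregate_subject, metrics_frame
from .windows import WindowSpec, build_stack


@dataclass
class SurrogateConfig:
    """Null-model settings: 50 randomization runs with common phases by default."""

    n_runs: int = 50
    mode: str = "common_phase"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise DynreconfError("n_runs must be >= 1")
        if self.mode not in ("common_phase", "independent_phase"):
            raise DynreconfError(f"unknown surrogate mode {self.mode!r}")


@dataclass
class SurrogateResult:
    """Per-subnetwork, per-metric means over runs (same units as raw metrics)."""

    mean: pd.DataFrame
    runs: list[pd.DataFrame] | None = None


def phase_randomize(
    ts: TimeSeriesMatrix,
    mode: str = "common_phase",
    rng: np.random.Generator | None = None,
) -> TimeSeriesMatrix:
    """Phase-randomize each region's series after Fourier transformation.

    Random phases are applied to the positive-frequency bins (DC and, for
    even-length series, the Nyquist bin are untouched) and conjugate-mirrored
    implicitly by the real inverse FFT, so the output is real with the exact
    input amplitude spectrum.  ``common_phase`` shares one phase vector
    across regions; ``independent_phase`` draws per region.
    """
    if mode not in ("common_phase", "independent_phase"):
        raise DynreconfError(f"unknown surrogate mode {mode!r}")
    if ts.n_volumes < 4:
        raise DynreconfError("phase randomization needs >= 4 volumes")
    rng = np.random.default_rng(rng)
    x = ts.values
    n = ts.n_volumes
    spec = np.fft.rfft(x, axis=1)
    n_bins = spec.shape[1]
    # bins 1..last are randomized; the last rfft bin is Nyquist iff n is even
    lo, hi = 1, n_bins - 1 if n % 2 == 0 else n_bins
    if mode == "common_phase":
        phases = rng.uniform(0.0, 2.0 * np.pi, size=hi - lo)
        rot = np.exp(1j * phases)[None, :]
    else:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(x.shape[0], hi - lo))
        rot = np.exp(1j * phases)
    spec[:, lo:hi] = spec[:, lo:hi] * rot
    surro = np.fft.irfft(spec, n=n, axis=1)
    return TimeSeriesMatrix(
        values=surro,
        tr_seconds=ts.tr_seconds,
        region_ids=ts.region_ids,
        subject_id=ts.subject_id,
        timepoint_id=ts.timepoint_id,
    )


def null_ensemble(
    ts: TimeSeriesMatrix,
    window_spec: WindowSpec,
    canonical: CanonicalPartition,
    config: SurrogateConfig,
    keep_runs: bool = False,
) -> SurrogateResult:
    """Average per-subnetwork reconfiguration metrics over surrogate runs.

    Each run re-seeds deterministically from ``config.seed`` (run *i* uses
    the i-th spawn of the seed sequence), phase-randomizes the input, and
    executes the full windows -> assignment -> metrics pipeline.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs: list[pd.DataFrame] = []
    for i, child in enumerate(children):
        try:
            surro = phase_randomize(ts, config.mode, np.random.default_rng(child))
            stack = build_stack(surro, window_spec)
            assignments = dynamic_assignment(stack, canonical)
            node = metrics_frame(assignments)
            runs.append(aggregate_subject(node, canonical))
        except DynreconfError as exc:
            raise DynreconfError(f"surrogate run {i} failed: {exc}") from exc
    mean = sum(r[list(METRICS)] for r in runs) / len(runs)
    return SurrogateResult(mean=mean, runs=runs if keep_runs else None)
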