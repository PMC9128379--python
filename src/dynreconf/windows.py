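"""Sliding-window connectivity.

Cuts a region x volume series into overlapping windows (specified in seconds
on the TR grid) and computes, per window, the matrix of absolute Fisher
r-to-z transformed Pearson correlations between all region pairs.  Windows
are either square (uniform weights) or Gaussian-tapered, in which case
weighted means/covariances implement the weighted correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    ConnectivityStack,
    DegenerateWindowError,
    DynreconfError,
    TimeSeriesMatrix,
    WindowSizingError,
)

#: Correlations are clipped to +/- (1 - CLIP_EPS) before arctanh so that the
#: Fisher z value stays finite on degenerate (perfectly correlated) inputs.
CLIP_EPS = 1e-7


@dataclass
class WindowSpec:
    """Sliding-window geometry and taper.

    Defaults follow the 60 s window / 10 s step convention; the shorter
    44 s window and the Gaussian taper (sigma = 3 TR) are the standard
    robustness variants.
    """

    length_seconds: float = 60.0
    step_seconds: float = 10.0
    shape: str = "square"
    gaussian_sigma_tr: float = 3.0

    def __post_init__(self) -> None:
        if self.length_seconds <= 0 or self.step_seconds <= 0:
            raise DynreconfError("window length and step must be positive")
        if self.shape not in ("square", "gaussian"):
            raise DynreconfError(f"unknown window shape {self.shape!r}")
        if self.gaussian_sigma_tr <= 0:
            raise DynreconfError("gaussian_sigma_tr must be positive")

    def length_volumes(self, tr_seconds: float) -> int:
        return int(round(self.length_seconds / tr_seconds))

    def step_volumes(self, tr_seconds: float) -> int:
        return max(1, int(round(self.step_seconds / tr_seconds)))


def make_windows(
    n_volumes: int, tr_seconds: float, spec: WindowSpec
) -> list[tuple[int, int, np.ndarray]]:
    """Enumerate window (start, length, weights) triples.

    Seconds are converted to volumes by rounding to the nearest integer;
    starts advance by the step while the window fits:
    ``floor((n_volumes - w) / s) + 1`` windows in total.
    Gaussian windows attach weights ``exp(-(t - center)^2 / (2 sigma^2))``
    centred at the window midpoint; square windows attach all-ones.
    """
    w = spec.length_volumes(tr_seconds)
    s = spec.step_volumes(tr_seconds)
    if w < 2:
        raise WindowSizingError(f"window of {w} volumes is too short")
    if w > n_volumes:
        raise WindowSizingError(
            f"window of {w} volumes does not fit in series of {n_volumes} volumes"
        )
    if spec.shape == "gaussian":
        t = np.arange(w, dtype=float)
        center = (w - 1) / 2.0
        weights = np.exp(-((t - center) ** 2) / (2.0 * spec.gaussian_sigma_tr**2))
    else:
        weights = np.ones(w)
    return [(start, w, weights) for start in range(0, n_volumes - w + 1, s)]


def _weighted_correlation(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of rows of ``x``.

    Reduces exactly to the ordinary Pearson correlation for uniform weights.
    """
    p = weights / weights.sum()
    mu = x @ p
    xc = x - mu[:, None]
    cov = (xc * p) @ xc.T
    var = np.diag(cov).copy()
    # zero variance up to fp noise: compare against the weighted mean square
    msq = (x * x) @ p
    degenerate = var <= 1e-24 * np.maximum(msq, np.finfo(float).tiny)
    if np.any(degenerate):
        bad = int(np.flatnonzero(degenerate)[0])
        raise DegenerateWindowError(
            f"region index {bad} has zero variance within the window"
        )
    sd = np.sqrt(var)
    return cov / np.outer(sd, sd)


def window_connectivity(
    ts: TimeSeriesMatrix, window: tuple[int, int, np.ndarray]
) -> np.ndarray:
    """Absolute Fisher-z connectivity matrix for one window.

    Pearson r (weighted for tapered windows) is clipped to ``|r| <= 1 - 1e-7``
    and transformed as ``|arctanh(r)|``.  The diagonal is set to NaN: it is
    excluded, not a connectivity value.
    """
    start, length, weights = window
    if start < 0 or start + length > ts.n_volumes:
        raise WindowSizingError(
            f"window [{start}, {start + length}) outside series of {ts.n_volumes} volumes"
        )
    try:
        r = _weighted_correlation(ts.values[:, start : start + length], weights)
    except DegenerateWindowError as exc:
        raise DegenerateWindowError(f"{exc} (window starting at volume {start})") from exc
    r = np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
    z = np.abs(np.arctanh(r))
    z = 0.5 * (z + z.T)  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(z, np.nan)
    return z


def build_stack(ts: TimeSeriesMatrix, spec: WindowSpec) -> ConnectivityStack:
    """Connectivity matrices for every window of ``ts``, ordered by start."""
    windows = make_windows(ts.n_volumes, ts.tr_seconds, spec)
    mats = np.stack([window_connectivity(ts, win) for win in windows])
    return ConnectivityStack(
        matrices=mats,
        window_starts=np.array([w[0] for w in windows], dtype=np.int64),
        window_length_volumes=windows[0][1],
        weights_profile=windows[0][2],
        region_ids=ts.region_ids,
        tr_seconds=ts.tr_seconds,
    )


class SlidingWindowConnectivity(TransformerMixin, BaseEstimator):
    """Transformer: :class:`TimeSeriesMatrix` -> :class:`ConnectivityStack`.

    A stateless sklearn-style wrapper over :func:`build_stack`; ``fit`` is a
    no-op kept for pipeline compatibility.
    """

    def __init__(
        self,
        length_seconds: float = 60.0,
        step_seconds: float = 10.0,
        shape: str = "square",
        gaussian_sigma_tr: float = 3.0,
    ):
        self.length_seconds = length_seconds
        self.step_seconds = step_seconds
        self.shape = shape
        self.gaussian_sigma_tr = gaussian_sigma_tr

    def _spec(self) -> WindowSpec:
        return WindowSpec(
            length_seconds=self.length_seconds,
            step_seconds=self.step_seconds,
            shape=self.shape,
            gaussian_sigma_tr=self.gaussian_sigma_tr,
        )

    def fit(self, X: TimeSeriesMatrix | None = None, y=None):
        self.spec_ = self._spec()
        return self

    def transform(self, X: TimeSeriesMatrix) -> ConnectivityStack:
        return build_stack(X, self._spec())
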