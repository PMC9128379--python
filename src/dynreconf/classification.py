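"""Cognitive-status classification from domain scores.

Seven neuropsychological domains (executive functioning, verbal memory,
information processing speed, verbal fluency, visuospatial memory, working
memory, attention) are standardized against a healthy-control (HC) reference
after residualizing age, sex and education on the HC cohort, separately per
time-point.  Cross-sectional status follows the conventional count rules:

* **CI**  (cognitively impaired):      z < -2   on >= 2 of 7 domains;
* **MCI** (mildly cognitively impaired): z < -1.5 on >= 2 of 7 domains,
  not meeting the CI rule (inclusive reading; a band-exclusive
  -2 <= z < -1.5 reading is available via ``mci_band_exclusive``);
* **CP**  (cognitively preserved):     everyone else.

Longitudinal status uses a practice-corrected reliable-change-style rule:
per domain, the follow-up minus baseline z-change is corrected by the mean
HC change and annualized by the inter-visit interval; a patient declines if
the corrected yearly change is -0.25 or worse on >= 2 of 7 domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import DynreconfError

DOMAINS: tuple[str, ...] = (
    "executive_functioning",
    "verbal_memory",
    "information_processing_speed",
    "verbal_fluency",
    "visuospatial_memory",
    "working_memory",
    "attention",
)

COVARIATES: tuple[str, ...] = ("age", "sex", "education")


@dataclass
class ClassificationConfig:
    """Thresholds of the status rules (all on the HC-referenced z scale)."""

    ci_threshold: float = -2.0
    mci_threshold: float = -1.5
    min_domains: int = 2
    decline_yearly_change: float = 0.25
    min_declining_domains: int = 2
    mci_band_exclusive: bool = False
    rci_sd_normalized: bool = False

    def __post_init__(self) -> None:
        if not self.ci_threshold < self.mci_threshold < 0:
            raise DynreconfError("need ci_threshold < mci_threshold < 0")
        if self.decline_yearly_change <= 0:
            raise DynreconfError("decline_yearly_change must be positive")


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    x = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DynreconfError(f"singular covariate design over {list(covariates)}")
    return x


def domain_z_scores(
    records: pd.DataFrame,
    domains: Sequence[str] = DOMAINS,
    covariates: Sequence[str] = COVARIATES,
    hc_label: str = "HC",
    min_hc: int = 10,
) -> pd.DataFrame:
    """Covariate-adjusted, HC-referenced z-scores per domain and time-point.

    For each domain and time-point a linear model of the raw score on the
    covariates is fit on the HC rows only; *all* rows are residualized
    against it, and residuals are standardized by the HC residual mean and
    sample SD of that time-point.  Adds ``z_<domain>`` columns and an
    ``average_cognition`` column (mean of the seven domain z-scores —
    descriptive only, never used for classification).
    """
    need = set(covariates) | set(domains) | {"group", "timepoint"}
    if not need.issubset(records.columns):
        raise DynreconfError(f"missing columns: {sorted(need - set(records.columns))}")
    out = records.copy()
    for d in domains:
        out[f"z_{d}"] = np.nan
    for tp, tp_idx in out.groupby("timepoint").groups.items():
        block = out.loc[tp_idx]
        hc = block[block["group"] == hc_label]
        if len(hc) < min_hc:
            raise DynreconfError(
                f"need >= {min_hc} HC reference rows at timepoint {tp}, got {len(hc)}"
            )
        x_hc = _design(hc, covariates)
        x_all = np.column_stack(
            [np.ones(len(block))] + [block[c].to_numpy(float) for c in covariates]
        )
        for d in domains:
            beta, *_ = np.linalg.lstsq(x_hc, hc[d].to_numpy(float), rcond=None)
            resid = block[d].to_numpy(float) - x_all @ beta
            resid_hc = hc[d].to_numpy(float) - x_hc @ beta
            sd = float(np.std(resid_hc, ddof=1))
            if sd == 0 or not np.isfinite(sd):
                raise DynreconfError(f"degenerate HC residual SD for domain {d} at {tp}")
            out.loc[tp_idx, f"z_{d}"] = (resid - float(resid_hc.mean())) / sd
    out["average_cognition"] = out[[f"z_{d}" for d in domains]].mean(axis=1)
    return out


def classify_cross_sectional(
    z: Mapping[str, float] | Sequence[float],
    config: ClassificationConfig | None = None,
) -> str:
    """CP / MCI / CI from seven domain z-scores (evaluation order: CI first)."""
    config = config or ClassificationConfig()
    values = np.asarray(
        [z[d] for d in DOMAINS] if isinstance(z, Mapping) else list(z), dtype=float
    )
    if values.shape != (len(DOMAINS),) or np.any(np.isnan(values)):
        raise DynreconfError("need exactly 7 non-missing domain z-scores")
    n_ci = int(np.sum(values < config.ci_threshold))
    if n_ci >= config.min_domains:
        return "CI"
    if config.mci_band_exclusive:
        n_mci = int(
            np.sum((values < config.mci_threshold) & (values >= config.ci_threshold))
        )
    else:
        n_mci = int(np.sum(values < config.mci_threshold))
    if n_mci >= config.min_domains:
        return "MCI"
    return "CP"


def classify_longitudinal(
    z_baseline: Sequence[float],
    z_followup: Sequence[float],
    hc_mean_change: Sequence[float],
    interval_years: float,
    config: ClassificationConfig | None = None,
    hc_sd_change: Sequence[float] | None = None,
) -> str:
    """stable / declining via the practice-corrected annualized change rule.

    Per domain: ``corrected = (z_followup - z_baseline) - mean HC change``,
    annualized by ``interval_years``; the domain declines when the yearly
    corrected change is ``<= -decline_yearly_change``.  With
    ``rci_sd_normalized`` the corrected change is first divided by the HC
    change SD (a classical RCI denominator) before annualization.
    """
    config = config or ClassificationConfig()
    if interval_years <= 0:
        raise DynreconfError("interval_years must be positive")
    zb = np.asarray(list(z_baseline), dtype=float)
    zf = np.asarray(list(z_followup), dtype=float)
    hc = np.asarray(list(hc_mean_change), dtype=float)
    if not zb.shape == zf.shape == hc.shape == (len(DOMAINS),):
        raise DynreconfError("need 7 baseline, follow-up and HC-change values")
    corrected = (zf - zb) - hc
    if config.rci_sd_normalized:
        if hc_sd_change is None:
            raise DynreconfError("rci_sd_normalized requires hc_sd_change")
        sd = np.asarray(list(hc_sd_change), dtype=float)
        if np.any(sd <= 0):
            raise DynreconfError("hc_sd_change must be positive")
        corrected = corrected / sd
    yearly = corrected / interval_years
    n_decl = int(np.sum(yearly <= -config.decline_yearly_change))
    return "declining" if n_decl >= config.min_declining_domains else "stable"


class CognitiveStatusClassifier(BaseEstimator):
    """Estimator: fit the HC reference, predict CP/MCI/CI and stable/declining.

    ``fit`` learns, per time-point and domain, the HC covariate model and
    residual distribution, plus the HC mean (and SD of) longitudinal change.
    ``transform`` appends z-score columns; ``predict`` returns the
    cross-sectional class per row; ``predict_longitudinal`` returns one
    stable/declining label per subject with both time-points.
    """

    def __init__(
        self,
        config: ClassificationConfig | None = None,
        covariates: Sequence[str] = COVARIATES,
        min_hc: int = 10,
    ):
        self.config = config
        self.covariates = covariates
        self.min_hc = min_hc

    def _config(self) -> ClassificationConfig:
        return self.config or ClassificationConfig()

    def fit(self, X: pd.DataFrame, y=None):
        """Learn HC reference models from a cohort table (one row per subject/visit)."""
        self.reference_ = X[X["group"] == "HC"].copy()
        scored = domain_z_scores(
            X, covariates=self.covariates, min_hc=self.min_hc
        )
        hc = scored[scored["group"] == "HC"]
        zcols = [f"z_{d}" for d in DOMAINS]
        tps = sorted(X["timepoint"].unique())
        if len(tps) >= 2:
            base = hc[hc["timepoint"] == tps[0]].set_index("subject_id")[zcols]
            fup = hc[hc["timepoint"] == tps[1]].set_index("subject_id")[zcols]
            common = base.index.intersection(fup.index)
            change = fup.loc[common] - base.loc[common]
            self.hc_mean_change_ = change.mean().to_numpy()
            self.hc_sd_change_ = change.std(ddof=1).to_numpy()
        else:
            self.hc_mean_change_ = None
            self.hc_sd_change_ = None
        self.timepoints_ = tps
        self.training_columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Z-score rows against the fitted HC reference (per time-point)."""
        ref_keys = set(zip(self.reference_["subject_id"], self.reference_["timepoint"]))
        x_keys = set(zip(X["subject_id"], X["timepoint"]))
        if ref_keys <= x_keys:  # X already contains the reference rows
            return domain_z_scores(X, covariates=self.covariates, min_hc=self.min_hc)
        combined = pd.concat([self.reference_, X], ignore_index=True)
        scored = domain_z_scores(
            combined, covariates=self.covariates, min_hc=self.min_hc
        )
        return scored.iloc[len(self.reference_) :].reset_index(drop=True)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scored = self.transform(X)
        cfg = self._config()
        zcols = [f"z_{d}" for d in DOMAINS]
        return np.array(
            [classify_cross_sectional(row, cfg) for row in scored[zcols].to_numpy()]
        )

    def predict_longitudinal(self, X: pd.DataFrame) -> pd.Series:
        if self.hc_mean_change_ is None:
            raise DynreconfError("longitudinal prediction needs >= 2 fitted time-points")
        scored = self.transform(X)
        cfg = self._config()
        zcols = [f"z_{d}" for d in DOMAINS]
        tps = self.timepoints_
        out: dict[str, str] = {}
        for sid, rows in scored.groupby("subject_id"):
            base = rows[rows["timepoint"] == tps[0]]
            fup = rows[rows["timepoint"] == tps[1]]
            if len(base) != 1 or len(fup) != 1:
                raise DynreconfError(f"subject {sid} lacks both time-points")
            interval = float(fup["interval_years"].iloc[0])
            out[sid] = classify_longitudinal(
                base[zcols].iloc[0],
                fup[zcols].iloc[0],
                self.hc_mean_change_,
                interval,
                cfg,
                hc_sd_change=self.hc_sd_change_,
            )
        return pd.Series(out, name="longitudinal_class")
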