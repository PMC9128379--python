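"""Synthetic cohorts with planted, group-dependent subnetwork switching.

Each subject's region x volume series is piecewise stationary: time is cut
into latent segments aligned to the sliding-window transition boundaries, and
within a segment signals follow a block covariance — correlation
``within_block_corr`` between regions currently in the same subnetwork,
``between_block_corr`` across subnetworks — realised through shared factors

    x_i(t) = sqrt(rho_b) g(t) + sqrt(rho_w - rho_b) g_{net(i,t)}(t)
             + sqrt(1 - rho_w) eps_i(t)

followed by AR(1) temporal smoothing.  Switch events move region rows between
blocks at segment boundaries: *mutual* events move >= 2 regions from one
source subnetwork to one target simultaneously, *independent* events move a
single region to a target no other region enters at that transition.  Every
planted event is recorded as ground truth, so recovery by the windowed
pipeline is testable.

Cohorts add phenotypes (age, sex, binary education), seven cognitive-domain
scores whose group means follow the CI < MCI < CP ordering, and a planted
declining/stable flag driving follow-up change.  All randomness derives
deterministically from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import DOMAINS
from .datatypes import (
    DEFAULT_NETWORKS,
    CanonicalPartition,
    DynreconfError,
    TimeSeriesMatrix,
)
from .windows import WindowSpec, make_windows

GROUPS = ("HC", "CP", "MCI", "CI")


@dataclass
class SimulationConfig:
    """Cohort-generation settings.

    Defaults emulate the acquisition this pipeline targets: 190 regions in 7
    subnetworks, 200 volumes at TR 2.2 s, two visits 5 years apart, groups
    HC/CP/MCI/CI with group-dependent switching.  Switch rates are expected
    events per region per window-transition; the mutual fraction is the share
    of planted switches that move together with another region.
    """

    n_regions: int = 190
    n_volumes: int = 200
    tr_seconds: float = 2.2
    n_networks: int = 7
    network_sizes: tuple[int, ...] | None = None
    within_block_corr: float = 0.6
    between_block_corr: float = 0.1
    ar1_coefficient: float = 0.2
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 15, "CP": 15, "MCI": 15, "CI": 15}
    )
    switch_rate_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.01, "CP": 0.01, "MCI": 0.02, "CI": 0.03}
    )
    mutual_fraction_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.8, "CP": 0.8, "MCI": 0.8, "CI": 0.8}
    )
    domain_shift_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "CP": -0.2, "MCI": -1.7, "CI": -2.5}
    )
    decline_fraction: float = 0.28
    decline_rate_per_year: float = 0.6
    n_decline_domains: int = 3
    n_timepoints: int = 2
    interval_years: float = 5.0
    confounded: bool = False
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            base = self.n_regions // self.n_networks
            extra = self.n_regions - base * self.n_networks
            self.network_sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_networks)
            )
        self.network_sizes = tuple(int(s) for s in self.network_sizes)
        if sum(self.network_sizes) != self.n_regions:
            raise DynreconfError(
                f"network_sizes sum {sum(self.network_sizes)} != n_regions {self.n_regions}"
            )
        if len(self.network_sizes) != self.n_networks:
            raise DynreconfError("one size per network required")
        if not 0 <= self.between_block_corr < self.within_block_corr < 1:
            raise DynreconfError(
                "need 0 <= between_block_corr < within_block_corr < 1"
            )
        if not 0 <= self.ar1_coefficient < 1:
            raise DynreconfError("ar1_coefficient must be in [0, 1)")
        if not self.group_sizes:
            raise DynreconfError("group_sizes is empty")
        for g in self.group_sizes:
            if g not in GROUPS:
                raise DynreconfError(f"unknown group {g!r}")
            for table, name in (
                (self.switch_rate_per_group, "switch_rate_per_group"),
                (self.mutual_fraction_per_group, "mutual_fraction_per_group"),
            ):
                if g not in table:
                    raise DynreconfError(f"{name} lacks group {g!r}")
        for g, f in self.mutual_fraction_per_group.items():
            if not 0 <= f <= 1:
                raise DynreconfError(f"mutual fraction for {g} outside [0, 1]")
        if self.n_timepoints not in (1, 2):
            raise DynreconfError("n_timepoints must be 1 or 2")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(f"r{i:03d}" for i in range(self.n_regions))

    @property
    def network_names(self) -> tuple[str, ...]:
        if self.n_networks == len(DEFAULT_NETWORKS):
            return DEFAULT_NETWORKS
        return tuple(f"N{i}" for i in range(self.n_networks))

    def canonical_partition(self) -> CanonicalPartition:
        """Block partition: the first ``network_sizes[0]`` regions in network 0, etc."""
        codes = np.repeat(np.arange(self.n_networks), self.network_sizes)
        return CanonicalPartition.from_codes(codes, self.region_ids, self.network_names)


@dataclass
class SwitchEvent:
    """One planted move of a region set between subnetworks at a window transition."""

    subject_id: str
    timepoint: str
    transition: int
    regions: tuple[str, ...]
    source: str
    target: str
    mutual: bool

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        if self.mutual != (len(self.regions) >= 2):
            raise DynreconfError("mutual flag must equal (|regions| >= 2)")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic cohort: every planted event plus design facts."""

    events: list[SwitchEvent] = field(default_factory=list)
    group_of_subject: dict[str, str] = field(default_factory=dict)
    planted_group_effect: dict[str, list[str]] = field(default_factory=dict)

    def events_for(self, subject_id: str, timepoint: str | None = None) -> list[SwitchEvent]:
        return [
            e
            for e in self.events
            if e.subject_id == subject_id
            and (timepoint is None or e.timepoint == timepoint)
        ]

    def to_records(self) -> list[dict]:
        return [asdict(e) for e in self.events]


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` produces."""

    timeseries: dict[tuple[str, str], TimeSeriesMatrix]
    table: pd.DataFrame
    truth: PlantedTruth
    config: SimulationConfig


def apply_switch_event(
    codes: np.ndarray, event: SwitchEvent, config: SimulationConfig
) -> np.ndarray:
    """Apply one event to a membership code vector, validating its consistency."""
    names = config.network_names
    idx = {n: i for i, n in enumerate(names)}
    rid = {r: i for i, r in enumerate(config.region_ids)}
    out = codes.copy()
    for r in event.regions:
        if r not in rid:
            raise DynreconfError(f"event names unknown region {r!r}: {event}")
        if names[codes[rid[r]]] != event.source:
            raise DynreconfError(
                f"region {r} is in {names[codes[rid[r]]]}, not claimed source "
                f"{event.source}: {event}"
            )
        out[rid[r]] = idx[event.target]
    return out


def _transition_boundaries(config: SimulationConfig) -> list[int]:
    """Volume index at which transition k takes effect: the midpoint of the
    symmetric difference between windows k and k+1, so window k is majority
    pre-switch and window k+1 majority post-switch."""
    windows = make_windows(config.n_volumes, config.tr_seconds, config.window_spec)
    w = windows[0][1]
    s = windows[1][0] - windows[0][0] if len(windows) > 1 else w
    return [start + int(round((w + s) / 2.0)) for start, _, _ in windows[:-1]]


def _plant_events(
    config: SimulationConfig,
    subject_id: str,
    timepoint: str,
    switch_rate: float,
    mutual_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[SwitchEvent]]:
    """Draw events and build the per-volume membership matrix."""
    names = config.network_names
    region_ids = config.region_ids
    codes = np.repeat(np.arange(config.n_networks), config.network_sizes)
    boundaries = _transition_boundaries(config)
    volume_codes = np.empty((config.n_regions, config.n_volumes), dtype=np.int64)
    events: list[SwitchEvent] = []
    prev_volume = 0
    expected = switch_rate * config.n_regions
    for t, boundary in enumerate(boundaries):
        volume_codes[:, prev_volume:boundary] = codes[:, None]
        prev_volume = boundary
        n_pairs = rng.poisson(expected * mutual_fraction / 2.0)
        n_indep = rng.poisson(expected * (1.0 - mutual_fraction))
        used_targets: set[int] = set()
        moved: set[int] = set()
        for _ in range(n_pairs):
            counts = np.bincount(
                np.delete(codes, list(moved)) if moved else codes,
                minlength=config.n_networks,
            )
            sources = [g for g in range(config.n_networks) if counts[g] >= 2]
            if not sources:
                continue
            src = int(rng.choice(sources))
            members = [
                i for i in np.flatnonzero(codes == src) if i not in moved
            ]
            pair = rng.choice(len(members), size=2, replace=False)
            regs = [members[pair[0]], members[pair[1]]]
            candidates = [
                g
                for g in range(config.n_networks)
                if g != src and g not in used_targets
            ]
            if not candidates:
                continue
            tgt = int(rng.choice(candidates))
            event = SwitchEvent(
                subject_id,
                timepoint,
                t,
                tuple(region_ids[i] for i in regs),
                names[src],
                names[tgt],
                mutual=True,
            )
            codes = apply_switch_event(codes, event, config)
            events.append(event)
            used_targets.add(tgt)
            moved.update(regs)
        for _ in range(n_indep):
            free = [i for i in range(config.n_regions) if i not in moved]
            if not free:
                continue
            reg = int(rng.choice(free))
            src = int(codes[reg])
            candidates = [
                g
                for g in range(config.n_networks)
                if g != src and g not in used_targets
            ]
            if not candidates:
                continue
            tgt = int(rng.choice(candidates))
            event = SwitchEvent(
                subject_id,
                timepoint,
                t,
                (region_ids[reg],),
                names[src],
                names[tgt],
                mutual=False,
            )
            codes = apply_switch_event(codes, event, config)
            events.append(event)
            used_targets.add(tgt)
            moved.add(reg)
    volume_codes[:, prev_volume:] = codes[:, None]
    return volume_codes, events


def generate_subject_timeseries(
    config: SimulationConfig,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    timepoint: str = "baseline",
    switch_rate: float | None = None,
) -> tuple[TimeSeriesMatrix, list[SwitchEvent]]:
    """One subject/visit's series with planted switching and its ground truth.

    Signals are zero-mean, unit-variance by construction (amplitude units are
    irrelevant to correlation-based analysis).
    """
    if group not in config.group_sizes:
        raise DynreconfError(f"group {group!r} not in group_sizes")
    rate = (
        switch_rate if switch_rate is not None else config.switch_rate_per_group[group]
    )
    volume_codes, events = _plant_events(
        config,
        subject_id,
        timepoint,
        rate,
        config.mutual_fraction_per_group[group],
        rng,
    )
    rho_w, rho_b = config.within_block_corr, config.between_block_corr
    g_global = rng.standard_normal(config.n_volumes)
    g_block = rng.standard_normal((config.n_networks, config.n_volumes))
    eps = rng.standard_normal((config.n_regions, config.n_volumes))
    cols = np.arange(config.n_volumes)
    innovations = (
        np.sqrt(rho_b) * g_global[None, :]
        + np.sqrt(rho_w - rho_b) * g_block[volume_codes, cols[None, :]]
        + np.sqrt(1.0 - rho_w) * eps
    )
    phi = config.ar1_coefficient
    x = np.empty_like(innovations)
    x[:, 0] = innovations[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, config.n_volumes):
        x[:, t] = phi * x[:, t - 1] + scale * innovations[:, t]
    ts = TimeSeriesMatrix(
        values=x,
        tr_seconds=config.tr_seconds,
        region_ids=config.region_ids,
        subject_id=subject_id,
        timepoint_id=timepoint,
    )
    return ts, events


def _planted_ordering(config: SimulationConfig) -> dict[str, list[str]]:
    groups = [g for g in GROUPS if config.group_sizes.get(g, 0) > 0]
    by_rate = sorted(groups, key=lambda g: config.switch_rate_per_group[g])
    by_mutual = sorted(
        groups,
        key=lambda g: config.switch_rate_per_group[g]
        * config.mutual_fraction_per_group[g],
    )
    by_indep = sorted(
        groups,
        key=lambda g: config.switch_rate_per_group[g]
        * (1 - config.mutual_fraction_per_group[g]),
    )
    return {
        "promiscuity": by_rate,
        "flexibility": by_rate,
        "cohesion": by_mutual,
        "disjointedness": by_indep,
    }


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Full synthetic cohort: time series, phenotype table, planted truth.

    Subject ids are ``<group><nn>``; one series per subject per time-point.
    Ages are drawn N(48, 11) (clipped to 20-75, advanced by the interval at
    follow-up), sex ~ Bernoulli(0.7) (1 = female, matching the usual cohort
    composition), higher education ~ Bernoulli(0.5).  Domain scores are
    group-mean-shifted unit normals; declining patients (a planted
    ``decline_fraction`` of non-HC subjects) lose ``decline_rate_per_year``
    z-units per year on ``n_decline_domains`` randomly chosen domains at
    follow-up.  With ``confounded=True`` age additionally scales the switch
    rate and depresses domain scores, for covariate-adjustment tests.
    """
    subjects: list[tuple[str, str]] = []
    for g in GROUPS:
        for i in range(config.group_sizes.get(g, 0)):
            subjects.append((f"{g}{i + 1:02d}", g))
    if not subjects:
        raise DynreconfError("group_sizes is empty")
    timepoints = ["baseline", "followup"][: config.n_timepoints]
    root = np.random.SeedSequence(config.seed)
    pheno_rng = np.random.default_rng(root.spawn(1)[0])
    series_seeds = root.spawn(len(subjects) * len(timepoints))

    truth = PlantedTruth(planted_group_effect=_planted_ordering(config))
    timeseries: dict[tuple[str, str], TimeSeriesMatrix] = {}
    rows: list[dict] = []
    seed_i = 0
    for sid, grp in subjects:
        truth.group_of_subject[sid] = grp
        age = float(np.clip(pheno_rng.normal(48.0, 11.0), 20.0, 75.0))
        sex = int(pheno_rng.random() < 0.7)
        education = int(pheno_rng.random() < 0.5)
        declining = bool(grp != "HC" and pheno_rng.random() < config.decline_fraction)
        decline_domains = pheno_rng.choice(
            len(DOMAINS), size=config.n_decline_domains, replace=False
        )
        base_scores = config.domain_shift_per_group[grp] + pheno_rng.standard_normal(
            len(DOMAINS)
        )
        rate = config.switch_rate_per_group[grp]
        if config.confounded:
            rate = max(0.0, rate * (1.0 + 0.02 * (age - 48.0)))
            base_scores = base_scores - 0.02 * (age - 48.0)
        for tp in timepoints:
            rng = np.random.default_rng(series_seeds[seed_i])
            seed_i += 1
            ts, events = generate_subject_timeseries(
                config, sid, grp, rng, timepoint=tp, switch_rate=rate
            )
            timeseries[(sid, tp)] = ts
            truth.events.extend(events)
            scores = base_scores.copy()
            if tp == "followup":
                scores = scores + 0.1 + pheno_rng.normal(0.0, 0.3, len(DOMAINS))
                if declining:
                    scores[decline_domains] -= (
                        config.decline_rate_per_year * config.interval_years
                    )
            row = {
                "subject_id": sid,
                "group": grp,
                "timepoint": tp,
                "age": age + (config.interval_years if tp == "followup" else 0.0),
                "sex": sex,
                "education": education,
                "interval_years": config.interval_years,
                "declining_truth": declining,
                "switch_rate": rate,
            }
            row.update({d: float(s) for d, s in zip(DOMAINS, scores)})
            rows.append(row)
    table = pd.DataFrame(rows)
    return Cohort(timeseries=timeseries, table=table, truth=truth, config=config)
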