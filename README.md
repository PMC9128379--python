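# dynreconf

Dynamic functional-network reconfiguration analysis for resting-state fMRI,
aimed at studies of cognitive decline (e.g. in multiple sclerosis): how often,
and in what pattern, do brain regions leave their canonical subnetwork over
the course of a scan, and does that switching behaviour differ between
cognitively preserved (CP), mildly impaired (MCI) and impaired (CI) patients
and healthy controls (HC)?

The package implements the full analysis chain as a library plus a CLI, and
ships a synthetic-cohort generator with planted, group-dependent switching so
every stage is testable end to end without patient data.

## Method

1. **Sliding-window connectivity.** Each region × volume BOLD matrix is cut
   into overlapping windows (default 60 s length, 10 s step on the TR grid;
   44 s and Gaussian-tapered σ = 3 TR variants included). Per window,
   connectivity is the absolute Fisher r-to-z transformed Pearson correlation
   between all region pairs.
2. **Iterative subnetwork reassignment.** Every window starts from the
   canonical partition into 7 resting-state subnetworks (DMN, FPN, DAN, VAN,
   visual, SMN, deep grey matter). The assignment quality of region *i* is

   &nbsp;&nbsp;&nbsp;&nbsp;*Q*ᵢ = (*C*within − *C*between) / (*C*within + *C*between),

   the mean connectivity to the region's own subnetwork minus the mean to all
   remaining regions, over their sum. Each iteration reassigns the worst
   region, argmin *Q*, to the subnetwork it connects to most strongly, and
   stops when the same region is selected twice in a row.
3. **Reconfiguration metrics.** Per region across the window sequence:
   **promiscuity** (fraction of subnetworks ever visited), **flexibility**
   (switches per transition), decomposed exactly into **cohesion** (switches
   made together with another region into the same target subnetwork) and
   **disjointedness** (switches made alone). Node values are averaged per
   canonical subnetwork, z-scored against the HC distribution per time-point,
   and averaged over the 7 subnetworks into a global value.
4. **Surrogate null.** Phase-randomized surrogates (shared phases across
   regions preserve the static correlation structure exactly) re-run through
   the whole pipeline, averaged over runs, give a per-subject null that
   isolates genuine dynamics from static connectivity.
5. **Cognition.** Seven neuropsychological domain scores are residualized on
   age/sex/education in the HC cohort and z-scored per time-point. CI: z < −2
   on ≥ 2 domains; MCI: z < −1.5 on ≥ 2 domains; decline: practice-corrected
   change of ≥ 0.25 z/year on ≥ 2 domains.
6. **Statistics.** OLS (cross-sectional) and random-intercept mixed models
   (longitudinal) with age/sex/education covariates, a gated Bonferroni
   ladder ({promiscuity, flexibility} → {cohesion, disjointedness} → 7
   subnetworks), and covariate-adjusted partial correlations.

## Worked example

```python
import numpy as np
from dynreconf import (SimulationConfig, WindowSpec, generate_cohort,
                       subject_reconfiguration, node_metrics)

cfg = SimulationConfig(n_regions=70, n_volumes=200,
                       group_sizes={"HC": 2, "CI": 2},
                       n_timepoints=1, seed=42)
cohort = generate_cohort(cfg)
partition = cfg.canonical_partition()
ts = cohort.timeseries[("CI01", "baseline")]
print(subject_reconfiguration(ts, WindowSpec(), partition).round(3))
```

prints this subject's per-subnetwork metric means:

```
         promiscuity  flexibility  cohesion  disjointedness
network
DMN            0.457        0.150     0.135           0.015
FPN            0.486        0.171     0.138           0.032
DAN            0.457        0.100     0.085           0.015
VAN            0.371        0.085     0.068           0.018
visual         0.514        0.112     0.082           0.029
SMN            0.371        0.109     0.071           0.038
DGM            0.314        0.065     0.032           0.032
```

A DMN flexibility of 0.150 means a DMN region changed subnetwork at 15% of
window transitions on average, and nearly all of that switching was mutual
(cohesion 0.135 vs disjointedness 0.015) — as expected for a CI-group subject
simulated with a high rate of mostly-mutual planted switches
(`cohort.truth.events_for("CI01")` lists all 51 of them). On single label
sequences:

```python
m = node_metrics(np.array([0, 1, 0, 1, 0]), n_networks=3)
print(f"flexibility={m.flexibility}, promiscuity={m.promiscuity:.3f}")
# flexibility=1.0, promiscuity=0.667
```

A region that switches at all 4 of 4 transitions has flexibility 1; visiting
2 of 3 subnetworks gives promiscuity 2/3.

The full pipeline is also available from the shell:

```bash
dynreconf all --seed 7 --profile test --out run/
```

which writes `cohort.csv`, per-subject time series, assignment matrices,
`metrics.csv` (raw and HC-referenced z), `surrogate_metrics.csv`,
`classification.csv`, `stats.csv` and a `manifest.json` recording every
effective parameter and seed.

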