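# mrnquant

Quantitative magnetic resonance neurography (MRN) of peripheral nerve.
`mrnquant` implements a complete analysis pipeline for dual-echo
T2-relaxometry studies of the tibial nerve: per-slice marker estimation from
magnitude images and nerve masks, aggregation along a proximal-to-distal leg
protocol, and the cohort-level statistical comparison of cases (e.g.
relapsing-remitting multiple sclerosis, RRMS) against healthy controls.
Because patient imaging data of this kind is not publicly shareable, the
package ships a synthetic cohort generator that emulates the acquisition and
the statistical structure of such a study, so the full pipeline is testable
end to end.

## The markers

From a pair of co-registered spin-echo magnitude images acquired at a short
echo time TE₁ = 14 ms and a long echo time TE₂ = 86 ms, each axial slice of
the nerve yields:

- **Apparent T2 relaxation time**
  `T2_app = (TE₂ − TE₁) / ln( SI(TE₁) / SI(TE₂) )` (ms), the transverse
  relaxation constant of nerve tissue under a mono-exponential decay
  `S(TE) = ρ · exp(−TE / T2_app)`;
- **Proton spin density** `ρ = SI(TE₁) / exp(−TE₁ / T2_app)` (a.u.), the
  signal extrapolated to TE = 0, proportional to mobile proton content;
- **T2w signal** (a.u.), the semiquantitative ROI mean of the long-echo
  (T2-weighted) image;
- **Cross-sectional area (CSA)** (mm²), the nerve mask's foreground pixel
  count times the squared pixel spacing.

Signal intensities are averaged over the nerve ROI *before* the formulas
are applied (ROI-first estimation), which suppresses the pixel-level noise
inherent to high-resolution nerve imaging.  Slices are grouped into the
protocol's anatomical regions — thigh (imaging slabs 1–2), lower leg
(slabs 3–4), and the left/right mid-to-distal thigh (slab 2 vs the
contralateral slab 5) — and compared with Mann-Whitney tests, Pearson
correlations against clinical and electrophysiologic covariates, and a
three-group ANOVA splitting cases at 3 years of symptom duration
(Tukey HSD post hoc).

## Worked example

```python
import mrnquant as mq

protocol = mq.AcquisitionProtocol(matrix=128, slices_per_slab=2)  # scaled grid
cohort = mq.CohortConfig(n_case=10, n_control=10)
frames = mq.simulate_measure_aggregate(protocol, cohort, seed=42)
results = mq.analysis_battery(frames["regions"], frames["clinical"])
for r in results.group_comparisons:
    print(f"{r.marker:>10} {r.region:<10} "
          f"cases {r.group_a_mean:7.1f} ± {r.group_a_sem:4.1f}   "
          f"controls {r.group_b_mean:7.1f} ± {r.group_b_sem:4.1f}   "
          f"U={r.u_statistic:5.1f}  p={r.p_value:.4f}")
```

prints

```
    t2_app thigh      cases    66.2 ±  1.2   controls    69.5 ±  1.3   U= 29.0  p=0.1212
    t2_app lower_leg  cases    62.4 ±  1.3   controls    65.6 ±  1.3   U= 31.0  p=0.1620
       rho thigh      cases   489.0 ± 29.5   controls   405.6 ± 10.7   U= 26.0  p=0.0757
       rho lower_leg  cases   482.0 ± 15.8   controls   404.8 ± 17.0   U= 12.0  p=0.0046
t2w_signal thigh      cases   132.7 ±  7.5   controls   117.6 ±  4.5   U= 26.0  p=0.0757
t2w_signal lower_leg  cases   120.9 ±  4.2   controls   108.9 ±  5.7   U= 31.0  p=0.1620
       csa thigh      cases    16.2 ±  0.7   controls    15.5 ±  0.5   U= 41.0  p=0.4950
       csa lower_leg  cases     8.3 ±  0.9   controls     8.8 ±  0.5   U= 45.0  p=0.7256
```

Each row is one group comparison: per-group mean ± SEM of the region-level
marker, the Mann-Whitney U statistic and its two-tailed p.  At this reduced
cohort size (10 vs 10) the configured case–control differences — lower
nerve T2_app, higher ρ in cases — are visible in the means but mostly not
yet significant; at the generator's default sizes (35 cases vs 30 controls)
the thigh T2_app and ρ comparisons are significant in essentially every
seeded run.

The same pipeline is available from a shell:

```bash
mrnquant run --seed 1 --out-dir out/          # simulate → ... → report.md
mrnquant generate --seed 1 --out-dir cohort/  # write NIfTI volumes + masks
mrnquant measure --in-dir cohort/             # per-slice marker CSV
mrnquant analyze --region-csv cohort/region_summary.csv \
                 --clinical-csv cohort/clinical.csv --out-dir stats/
```

`run` writes `slice_measurements.csv`, `region_summary.csv`, `results.csv`,
`results.json` and a markdown report whose every number traces back to a
row of `results.csv`.

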