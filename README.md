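# pm2pim

Process-mining conformance checking and predictive what-if impact modeling
for clinical event logs, built around a chemotherapy outpatient pathway.

Hospital process teams can usually *diagnose* workflow deviations from
their information-system event logs, but rarely *quantify* what fixing
them would buy.  `pm2pim` closes that gap: it reads IEEE-XES or CSV event
logs (or generates a calibrated synthetic log), checks every case against
a strictly sequential seven-step normative pathway by optimal alignment,
classifies the deviations (skipped steps, resequencing, rework loops,
extra activities) with root causes, and then *remodels* the log under
improvement scenarios to forecast the gain in two KPIs — cycle time and
workload — with paired statistical validation and a frequency x impact
decision matrix.

## The model in brief

For a trace $\sigma$ and the sequential model $M$ (7 activities), the
optimal alignment minimizes unit-cost log/model moves; replay fitness is

$$\text{fitness}(\sigma) = 1 - \frac{\text{cost}(\sigma, M)}{|\sigma| + |M|},$$

precision is escaping-edges precision over the aligned model runs, and the
F1-score is the harmonic mean of fitness and precision.  A scenario $S$
removes a set of classified deviations; remodeling deletes rework events
and recovers their attributed delays deterministically, and each KPI's
forecast improvement follows the reduction equation

$$\text{Reduction\%} = \frac{BV - SV}{BV} \times 100,$$

with $BV$/$SV$ the baseline and scenario means over paired per-case KPIs.
Validation uses the paired $t = \bar d / (s_d/\sqrt n)$ with Cohen's
$d = \bar d / s_d$, plus Wilcoxon signed-rank and Friedman tests on the
three-way comparison.  See `docs/methods.md` for assumptions, calibration
and limitations.

## Worked example

```python
from pm2pim import (GeneratorConfig, generate_log, default_model, align_log,
                    classify_deviations, full_adherence_filter,
                    scenario_defaults, run_scenario)

model = default_model()
log = generate_log(GeneratorConfig(), seed=42)   # 214 cases, 1254 events
_, adherent = full_adherence_filter(log, model)
records = classify_deviations(align_log(log, model), log, model)
current, full = scenario_defaults()
for scenario in (current, full):
    res = run_scenario(log, records, scenario, model)
    print(f"{scenario.name}: cycle -{res.cycle.reduction_pct:.2f}%, "
          f"workload -{res.workload.reduction_pct:.2f}%")
print(f"strictly adherent cases: {adherent}")
```

prints

```
Current Optimization: cycle -7.96%, workload -5.98%
Full Adherence: cycle -11.94%, workload -9.01%
strictly adherent cases: 27
```

Reading: eliminating the billing-correction rework and resequencing
(the *current optimization* scenario) shortens the mean patient cycle time
by about 8% and staff workload by about 6%; enforcing the full normative
sequence (removing every classified deviation) yields about 12% and 9%.
Exactly 27 of the 214 cases already execute the pathway perfectly (all
seven steps, no extras, canonical order, hence workload 7.00).

The same pipeline runs from the shell:

```bash
pm2pim run --seed 42 --out out/        # all CSV/JSON artifacts
pm2pim generate --out synthetic.xes    # just the calibrated log
```

`out/` then contains `kpi_results.csv` (paired per-case KPIs),
`kpi_means.csv`, `kpi_statistics.csv` (t/Wilcoxon/Friedman table),
`sensitivity.csv` (OFAT delay perturbation), `decision_matrix.csv`,
conformance `metrics.csv`, the deviation records, figure-data files
(Sankey flows, deviation map, scenario bars) and a `run_log.json` with the
seed and configuration hash; a fixed seed makes every artifact
byte-identical across runs.

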