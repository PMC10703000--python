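# evoimmune

Mechanistic modelling of murine colorectal tumors treated with
checkpoint-blockade immunotherapy (anti-PD-1 + anti-CTLA-4) and the
hypoxia-activated prodrug evofosfamide, for researchers studying why
evofosfamide sensitizes hypoxic tumors to immunotherapy.

The core is a two-state ODE model of tumor volume T(t) (mm³) and the
well-vascularized tumor fraction V(t) = 1 − H(t) (H = hypoxic fraction):

    dT/dt = k_T·T − (μ_T + Σ_l γ_i·e^{−r_i(t−t_i^l)}·ℋ(t−t_i^l)) · T·V
    dV/dt = (k_V + Σ_j γ_e·e^{−r_e(t−t_e^j)}·ℋ(t−t_e^j)) · (1−V) − μ_V·(T/T_c)·V

Tumor grows exponentially at k_T and is killed by the immune system
preferentially in well-vascularized tissue (baseline rate μ_T). Each
immunotherapy dose at t_i^l transiently raises the kill rate by γ_i
(washout r_i); each evofosfamide dose at t_e^j transiently raises the
re-vascularization rate by γ_e (washout r_e); tumor growth erodes
vascular adequacy through the μ_V coupling (T_c = 1000 mm³, the volume
unit of that term; see `docs/methods.md`). Evofosfamide has no direct
cytotoxic term — it acts purely by re-oxygenating the tumor.

On top of the model the package provides:

* a synthetic six-arm cohort generator emulating the experimental
  protocol (caliper volumes every 2–3 days over days 6–39, hypoxia
  imaging at days 12 and 17, evofosfamide daily on days 13–17,
  immunotherapy on configurable days);
* staged Bayesian calibration via ensemble MCMC — growth/immunotherapy
  rates on the evofosfamide-free arms, then the evofosfamide rates, then
  strict out-of-sample prediction of the normoxic combination arm, with
  sensitivity-ranked single-parameter re-calibration when the prediction
  fails (concordance below 0.8);
* time-resolved Sobol total-effect indices (Saltelli sampling, Jansen
  estimator) for ranking parameter influence along the timeline;
* prediction metrics: Lin's concordance correlation coefficient (CCC),
  Pearson correlation, floored mean absolute percent error, and the
  between-arm tumor-burden reduction.

## Worked example

```python
from evoimmune import (TreatmentSchedule, burden_reduction,
                       posterior_mean_parameters, simulate)

params = posterior_mean_parameters()       # published calibrated rates
immuno = (7.0, 10.0, 13.0)
evo = (13.0, 14.0, 15.0, 16.0, 17.0)
alone = simulate(params, TreatmentSchedule(immuno_days=immuno), 100.0, 0.2)
combo = simulate(params, TreatmentSchedule(immuno_days=immuno, evo_days=evo),
                 100.0, 0.2)
print(round(alone.T_series[-1], 1), round(combo.T_series[-1], 1))
print(round(burden_reduction(alone, combo, at=39.0), 2))
```

prints

```
19512.4 11522.1
40.95
```

i.e. starting from a 100 mm³ hypoxic tumor (80 % hypoxic fraction), the
day-39 volume under immunotherapy alone is 19 512 mm³, adding the
evofosfamide course drops it to 11 522 mm³ — a 40.95 % reduction in
final tumor burden. The other headline number, the immunotherapy
kill-rate increase required to explain the *normoxic* combination arm,
is printed by the report command:

```
$ evoimmune report
...
gamma_i fold change (scenario VI / shared): 18.6
```

The `analysis/` scripts run the full study on synthetic cohorts:
`01_simulate_arms.py` (forward simulation of all six arms),
`02_generate_cohort.py` → `03_staged_calibration.py` (parameter
recovery; stage-3 predictive CCC 0.848 on the default cohort),
`04_designed_failure.py` (an 18-fold inflated γ_i in the normoxic
combination arm is diagnosed and recovered with fold change 21, CCC
0.99), `05_sensitivity.py` (Sobol rankings per protocol) and
`06_burden_reduction.py`. Each writes its tables under `results/`.

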