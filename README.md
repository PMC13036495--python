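# filamech

Mechanics and kinetics of nucleoprotein filaments on nucleic-acid tethers,
from single-molecule magnetic-tweezers traces.

Innate-immune receptors such as MDA5 recognize long double-stranded RNA by
cooperatively polymerizing into filaments along it, stiffening the tether,
and — with ATP — compacting it into a tight ribonucleoprotein complex.
Magnetic tweezers resolve this process one molecule at a time: a bead
tethered by a single ~3 kbp dsRNA reports tether extension under calibrated
force and torque at camera rate. `filamech` is the quantitative pipeline
for such experiments, aimed at single-molecule biophysicists who need
reproducible, scriptable versions of analyses that are usually done by
hand:

* **WLC mechanics** — the inextensible worm-like chain force law
  `F(L) = (k_BT/L_p)[1/(4(1−L/L_c)²) − 1/4 + L/L_c]`, its closed-form
  stretching energy, and parameter estimation in the energy domain
  (integrate the force-extension trace, fit
  `E(L) = ¼ k_BT L²(2L−3L_c)/(L_p L_c (L−L_c))`), which suppresses the
  Brownian noise that corrupts direct force-law fits;
* **event kinetics** — nucleation waiting times (baseline + 3σ crossing with
  dwell), filament formation and compaction rates from 20 s / 50 s
  sliding-window slopes with detection limits, rupture-event detection
  (2σ / 5 s rule), and four-way trace classification
  (fully/partially compacted, dissociated, extended);
* **binding inference** — fractional occupancy from persistence lengths via
  `α = (√(1/L_p,i) − √(1/L̄_p)) / (√(1/L_p,sat) − √(1/L̄_p))`, binomial
  errors `δf = √(f(1−f)/N)`, and a bootstrap-averaged weighted fit of the
  Hill isotherm `α(c) = cⁿ/(K_Dⁿ + cⁿ)`;
* **a synthetic trace generator** — seeded, ground-truth-labeled traces
  (assembly, compaction with ruptures, force ramps, rotation-extension,
  occupancy counts) with the statistical structure the estimators assume,
  so the whole pipeline is testable without instrument data.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

Simulate a filament-assembly trace at 0.1 pN and recover its kinetics:

```python
import filamech as fm

truth = fm.GroundTruth()            # nucleation 0.062/s, growth 8 monomers/s, ...
cfg = fm.SimulationConfig(duration=200.0, seed=7)
trace = fm.simulate_assembly_trace(cfg, truth)

wait = fm.detect_nucleation(trace)
region = fm.propose_regions(trace)["formation"]
nm_per_s = fm.formation_rate(trace, region)
monomers = fm.monomer_rate(nm_per_s, truth.delta_ext_full(0.1))
print(f"waiting time {wait:.1f} s, growth {nm_per_s:.2f} nm/s = {monomers:.2f} monomers/s")
```

prints

```
waiting time 11.1 s, growth 9.54 nm/s = 8.14 monomers/s
```

i.e. this trace nucleated 11.1 s after the protein flush and grew at
8.1 monomers/s (generating value 8; the per-trace scatter averages out over
a cohort). Fitting tether mechanics from a simulated force ramp:

```python
cfg = fm.SimulationConfig(duration=60.0, seed=1,
                          force_protocol=fm.ForceProtocol("ramp", start=0.1, stop=8.0))
ramp = fm.simulate_force_ramp(cfg, fm.WLCParams(lp=45.0, lc=896.0), noise_sd=30.0)
fit = fm.fit_wlc_integrated(fm.ForceExtensionCurve(ramp.extension, ramp.force))
print(f"Lp {fit.lp:.1f} nm, Lc {fit.lc:.1f} nm, accepted={fit.accepted}")
```

prints

```
Lp 44.8 nm, Lc 896.7 nm, accepted=True
```

The same stages are available from the shell:

```
filamech simulate --protocol assembly --duration 200 --n-traces 5 --seed 0 --out traces/
filamech run traces/manifest.tsv --out report.json
filamech fit-wlc traces/ramp_000.tsv
filamech hill occupancy.tsv --nboot 1000 --seed 1
```

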