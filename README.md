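# dendrosim

Stochastic simulation of dendritic field elaboration, built to study a
basic developmental question: how can a neuron grow a *large* dendritic
field whose size is nevertheless *reproducible* from animal to animal?

The package is aimed at computational neuroscientists and quantitative
developmental biologists.  It treats dendrite growth as a birth-death
process over a grown-length coordinate, simulates it exactly, summarises
field sizes and their variability over ensembles of neurons, scans the
kinetic parameter plane, and ships the two rank-based dispersion tests
(Conover squared-ranks and Siegel-Tukey) used to compare field-size
variance between genotypes, together with a synthetic measurement
generator to exercise them.

## The model

All dendritic tips of a neuron elongate at a common constant speed, so a
single length coordinate *r* (μm) indexes growth.  Per μm grown, each of
the *n* active tips independently

* **branches** with rate *k_b* (μm⁻¹) — one tip becomes two, or
* **terminates** with rate *k_t* (μm⁻¹) — the tip stops, leaving a
  terminal point at the current *r*.

This is a linear birth-death process in *r*; the Gillespie algorithm
samples it exactly: the gap to the next event is
Δr = −log x₁ / (n (k_b + k_t)) with x₁ uniform on (0, 1], and the event
is a branch iff x₂ < k_b/(k_b + k_t).  A neuron starts with *N₀* = 30
tips and runs until *n* = 0, which is certain when Δk = k_t − k_b > 0.

Because a growing tip wanders diffusively, the radial distance of a
terminal point from the origin of growth is modelled as R = √r (Brownian
mapping).  The per-neuron field radius **R95** is the 95th percentile of
the terminal-point distances.  Ensembles (typically 100 neurons) are
summarised by mean, SD, median and CV of R95; the CV is the measure of
field-size robustness.  The characteristic field scale of a subcritical
stage is √(1/Δk).

A **two-stage schedule** switches (k_b, k_t) the first time *r* crosses a
threshold (100 μm in the standard presets), modelling an early
growth-favouring phase followed by a termination-favouring phase.

## Worked example

```python
from dendrosim import GrowthSchedule, simulate_ensemble, summarize_ensemble

for name, (kb, kt) in {"Tm20 wild type": (0.360, 0.594),
                       "Tm20 babo mutant": (0.322, 0.431)}.items():
    schedule = GrowthSchedule.one_stage(kb, kt, n0=30)
    s = summarize_ensemble(simulate_ensemble(schedule, 100, master_seed=1))
    print(name, round(s.mean_r95, 2), round(s.cv_r95, 1))
```

prints

```
Tm20 wild type     mean R95 = 3.19 ± 0.59 μm (CV 18.4%)
Tm20 babo mutant   mean R95 = 4.29 ± 0.96 μm (CV 22.4%)
```

i.e. the measured wild-type Tm20 kinetics confine dendrites to ~3 μm — a
single medulla column — with a CV near 20%, while the *babo*-mutant rates
(weaker termination) enlarge the field and its variability.  The
size-robustness trade-off and its two-stage resolution
(`examples/03_size_vs_robustness.py`):

```
one-stage Δk=0.005   mean R95 =  9.78 μm   CV =  51.5%
one-stage Δk=0.001   mean R95 = 11.25 μm   CV =  60.4%
two-stage            mean R95 = 10.42 μm   CV =  25.3%
```

Constant rates only reach the ~11 μm wide-field scale near criticality,
where the size fluctuates wildly; the two-stage schedule reaches it with
near-baseline variability.  Each script in `examples/` is a short
narrative of one capability (single neurons, ensembles, parameter scans,
dispersion testing, N₀ calibration).

A thin CLI wraps the same functions:

```bash
dendrosim simulate --preset tm20_wt --seed 1 --out runs/tm20
dendrosim scan --quick --out runs/grid
dendrosim synth --genotype wt 13.5 1.3 30 --genotype mut 13.4 2.5 25 \
    --seed 1 --out m.csv --compare wt mut
```

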