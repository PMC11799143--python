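# thinktime

How long should a person think before answering a simple perceptual
question?  The classical speed–accuracy trade-off (SAT) says accuracy keeps
creeping up with deliberation time, so more thinking is never worse.  Under
*resource rationality*, thinking itself carries a cost — cognitive load,
irritation — so the *net* value of deliberation peaks early and then falls.
The practical consequence is a very cheap intervention for crowdsourced
judgment work: impose a short enforced wait (about 1 s) before the response
buttons appear, and accuracy improves without the irritation that a longer
wait (2.5 s) produces.

`thinktime` implements both halves of that argument:

* **A simulator** of the grid task ("are more than 50% of the tiles in this
  50×50 grid black?") as Metropolis–Hastings anchoring-and-adjustment, with
  thinking-cost schedules and optimal-stopping (peak-time) statistics.
* **A measurement pipeline** for the corresponding waiting-time experiment:
  time-normalized mouse-trajectory AUC, RT-category accuracy, cumulative RT
  distributions, irritation scoring, and effect sizes (Cliff's δ, η²,
  Holm-adjusted pairwise comparisons).
* **A synthetic-data generator** that emulates the experiment's design
  (three waiting-time groups × four stimulus proportions, with known
  injected effects) so the pipeline is fully testable without participant
  data.

## The model

An estimate *v*<sub>t</sub> of the black-tile proportion starts from an
anchor *v*<sub>0</sub> ~ N(0.5, *b*) and is adjusted *T* = 150 times.  At
each step a proposal δ ~ N(0, 0.05) is accepted by the Metropolis–Hastings
rule under the target density N(*C*<sub>prop</sub>, *b*) truncated to
[0, 1], with *b* = 0.1 and *C*<sub>prop</sub> ∈ {0.55 (difficult), 0.65
(easy)}.  A chain is correct at time *t* if *v*<sub>t</sub> > 0.5.
Averaging over 1,000 chains gives the accuracy curve
ThinkBenefit<sub>t</sub> (rescaled so its maximum is 1); a linear cost
schedule ThinkCost<sub>t</sub> = *c*<sub>max</sub>·*t*/*T* with
*c*<sub>max</sub> ∈ {0 (SAT), 0.50 (resource-rational)} gives

&nbsp;&nbsp;&nbsp;&nbsp;TotalBenefit<sub>t</sub> = ThinkBenefit<sub>t</sub> − ThinkCost<sub>t</sub>.

The per-individual statistic is the step at which TotalBenefit peaks; its
distribution over 500 simulated individuals contrasts the two regimes:
resource-rational peaks are *earlier* and in a *narrower range*.

## Worked example

```python
from thinktime import SimulationConfig, compare_cost_regimes

cfg = SimulationConfig(c_prop=0.55, seed=1)   # difficult condition, full scale
regimes = compare_cost_regimes(cfg, (0.0, 0.5))
for cost, summary in regimes.items():
    print(f"max_cost={cost}: mean={summary.mean:.2f} "
          f"min={summary.min} max={summary.max}")
```

prints

```
max_cost=0.0: mean=93.00 min=26 max=150
max_cost=0.5: mean=22.99 min=7 max=48
```

With no thinking cost the total-benefit peak wanders over most of the
150-step horizon (mean ≈ 93 of 150 adjustment steps, range 26–150): once
accuracy plateaus, essentially any late step can be the argmax.  Adding the
linear cost pulls every individual's peak into a narrow early window (mean
≈ 23 steps, range 7–48) — the model's case for stopping, and for waiting,
early.

The same objects drive the CLI:

```bash
thinktime simulate --out sim/                   # 2 difficulties x 2 cost regimes
thinktime synth --out data/ --seed 7            # synthetic experiment (3 groups x 40 participants)
thinktime analyze --trials data/trials.csv \
    --trajectories data/trajectories.csv \
    --ratings data/ratings.csv --out analysis/
```

`analyze` ends with a summary like (synthetic data, seed 3):

```
Trials excluded (> 6 s): 2.1%
...
accuracy_difficult: F = 139.98, p = 9.168e-32, eta² = 0.705
irritation_2.5s_vs_1s: W = 1005.0, p = 0.0001863, Cliff's delta = 0.509
```

i.e. the pipeline recovers the effects the generator injected: waiting
improves difficult-stimulus accuracy (0.66 → 0.75 → 0.77 across the 0 s /
1 s / 2.5 s groups), trajectory AUC grows with response time, and the 2.5 s
wait is the more irritating one.

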