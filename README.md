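# tugtrap

Stochastic tug-of-war of kinesin and dynein on a trapped cargo: simulation
and analysis of optical-trap stall-force records.

## The problem

Phagosomes and other organelles carry both plus-end (kinesin) and
minus-end (dynein) microtubule motors and move bidirectionally. In an
optical trap a single phagosome produces an alternating sequence of
kinesin- and dynein-driven stalls, often reversing direction within half a
second. `tugtrap` implements the quantitative model that explains this
behavior — opposing motors engage stochastically and independently, like
tosses of a coin — and the analysis pipeline that extracts its statistics
from position-time records. It is written for single-molecule biophysicists
who want to reproduce the model's predictions, generate realistic synthetic
trap data with ground truth, or run the event-detection pipeline on their
own records.

The core quantities:

* **Occupancy.** Only motors in the cargo-microtubule contact zone
  (`A_contact`, ~4% of the surface of a 750-nm cargo) can engage. With
  `Nd = 240` dyneins and `Nk = 40` kinesins total, the zone holds
  `Binomial(N, 0.04)` motors of each species, and the probability that a
  winning dynein team (>= 6 x 1.1 pN) and at least one 6-pN kinesin are
  both available is

      P(X >= 6 | 240, 0.04) x P(Y >= 1 | 40, 0.04) = 0.74,

  the predicted fraction of rapid reversals (inactive time < 0.5 s).
* **Kinetics.** Zone motors bind/unbind with rates `k_on`, `k_off`; the
  bound fraction follows `C(t) = C_eq (1 - e^{-(k_on+k_off) t})`, and the
  time for >= 6 of 10 dyneins (or >= 1 of 2 kinesins) to first assemble is
  a birth-death hitting time, ~0.57 s (0.1 s) — both teams in ~0.5 s.
* **Coin tossing.** Labeling stalls K/D, consecutive pairs DD/DK/KD/KK
  each occur at ~25% under a fair, memoryless coin.

## Worked example

```python
from tugtrap import OccupancyModel, joint_reversal_probability
from tugtrap.synth import TraceGenConfig, generate_trace
from tugtrap.pipeline import analyze_trace

print(f"{joint_reversal_probability(OccupancyModel()):.4f}")
# 0.7406

trace, truth = generate_trace(TraceGenConfig(n_events=40), seed=1)
result = analyze_trace(trace)
print(len(result["stalls"]), len(result["pairs"]))
# 40 39
rev = [p for p in result["pairs"] if p.pair_type in ("DK", "KD")]
print(f"{sum(p.is_rr for p in rev)}/{len(rev)} reversals rapid")
# 18/23 reversals rapid
```

The first number is the occupancy model's joint probability: 74% of
cargo-filament encounters have both a >= 6-dynein team and a kinesin
available, so ~74% of reversals should happen within 0.5 s. The generated
trace contains 40 programmed stalls; the pipeline recovers all 40 and
types the 39 consecutive pairs, and the rapid fraction among detected
reversals (18/23 ~= 0.78 on this single trace) fluctuates around the
prediction — at study scale (~2000 reversal pairs) it converges to 0.74
within binomial error.

The `analysis/` directory holds the numbered drivers that walk the whole
study — occupancy table, kinetics, coin-toss statistics, trace synthesis,
detection/recovery scoring, reversal statistics — each writing its tables
under `results/`. A `tugtrap` CLI (`simulate`, `detect`, `occupancy`,
`kinetics`, `coin`, `report`) wraps the same functions for shell use.

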