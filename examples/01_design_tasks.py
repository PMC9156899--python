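"""Generate the two task trial sets and realize a day's bonus.

The risk task pits a guaranteed +-$0.50 against a two-outcome lottery whose
winning probability is fully known or partly occluded; the intertemporal
task pits a smaller "this week" reward against a larger delayed one.
"""

from emaecon import tasks

gain = tasks.generate_risk_trials("gain", seed=1)
loss = tasks.generate_risk_trials("loss", seed=1)
itc = tasks.generate_itc_trials("immediate0", seed=1)

print(f"risk gain: {len(gain)} trials "
      f"({sum(t.A == 0 for t in gain)} known-risk, {sum(t.A > 0 for t in gain)} ambiguity)")
print(f"risk loss: {len(loss)} trials, guaranteed = {loss[0].guaranteed:+.2f}")
print(f"intertemporal: {len(itc)} trials, delays {sorted({t.d_delayed for t in itc})} days")

# one completed task prompt -> one trial drawn and played for real money
day = {"risk-gain": [(t, 1) for t in gain[:10]], "itc": [(t, 0) for t in itc[:10]]}
bonus = tasks.realize_bonus(day, rng_seed=7)
print(f"bonus drawn from {bonus.source_task}: ${bonus.realized_amount:.2f} (cap $6.60)")
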