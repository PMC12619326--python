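"""Simulation-based power for the streak design.

How often does a paired t-test on per-participant fitted serial-dependence
amplitudes detect a 1-deg cued-vs-uncued amplitude difference with 18
participants and 648 trials?  (Reduce n_sims for a quick look; 1000
simulations reproduce the full protocol.)
"""

from serialdep.generate import DesignSpec
from serialdep.power import PowerConfig, estimate_power

cfg = PowerConfig(
    design=DesignSpec.exp1(n_participants=18, n_trials=648),
    effect_difference=1.0,
    baseline_amplitude=2.0,
    n_sims=200,
    alpha=0.05,
    seed=31,
)
res = estimate_power(cfg)
print(f"estimated power: {res.power:.3f}")
print(f"95% Monte-Carlo CI: ({res.mc_ci[0]:.3f}, {res.mc_ci[1]:.3f})")
print(f"rejections: {res.rejected_count}/{res.n_sims}")
print(
    "\nPower is the fraction of simulated experiments in which the paired"
    "\nt-test rejects at alpha = 0.05; near 0.9+ the design is well powered"
    "\nfor a 1-deg amplitude difference."
)
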