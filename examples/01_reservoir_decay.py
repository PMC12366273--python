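"""Reservoir half-life decay and media-exchange arithmetic.

Builds the default growth-factor table, shows how a reservoir's
concentration decays between media exchanges, and how full and half
exchanges reset it.
"""

import gradientchip as gc

factors = gc.load_default_factors()
media = gc.load_default_media()

igf = factors["IGF-1"]
print(f"IGF-1: D = {igf.diffusivity} um^2/s, half-life = {igf.half_life} s, "
      f"EC50 = {igf.ec50} ng/mL, k = {igf.decay_rate:.3e} 1/s")

state = gc.ReservoirState(0.0, {"IGF-1": igf.supplemented_conc})
for hours in (0, 0.4, 1, 2, 6):
    c = gc.reservoir_concentration(state, igf, hours * 3600.0)
    print(f"  after {hours:4.1f} h in the channel: {c:7.3f} ng/mL")

# a half exchange mixes decayed channel media 1:1 with fresh media
event = gc.MediaEvent(6 * 3600.0, ("left",), "half", media["vascular"])
after = gc.apply_media_event(state, event, factors)
print(f"after a half exchange at 6 h: IGF-1 = "
      f"{after.concentration_at_event['IGF-1']:.3f} ng/mL "
      "(midway between the decayed level and the fresh 15 ng/mL)")

sched = gc.build_gradient_schedule(media=media)
print(f"default 31-day gradient schedule: {len(sched.events)} media events, "
      f"inversion at day 17")
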