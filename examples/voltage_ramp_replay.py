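"""Replaying a voltage command through the Kv1.3 model (hump current).

Feeds a slow depolarizing ramp (-55 to +50 mV over 4 s, standing in for
a membrane-potential trace recorded from a T cell) through the gating
model of ~330 channels.  The current shows the characteristic hump:
silent until about -40 mV, rising steeply as channels activate, then
collapsing as slow C-type inactivation overtakes the ramp.
"""

import numpy as np

from kv13tcell import ChannelPopulation, Kv13Model, replay_voltage_command

model = Kv13Model()
pop = ChannelPopulation(330)  # resting T-cell expression level

t = np.arange(0.0, 4000.0, 1.0)
v = -55.0 + (50.0 + 55.0) * t / t[-1]
trace = replay_voltage_command(t, v, pop, model)

i_peak = int(np.argmax(trace.i_pA))
onset_v = v[trace.i_pA > 0.05 * trace.i_pA[i_peak]][0]
print(f"command: {v[0]:+.0f} -> {v[-1]:+.0f} mV ramp over {t[-1] / 1000:.0f} s, N = {pop.n_channels}")
print(f"current onset (5% of peak) near {onset_v:+.1f} mV")
print(f"peak current {trace.i_pA[i_peak]:.1f} pA at {v[i_peak]:+.1f} mV")
print(f"current at ramp end ({v[-1]:+.0f} mV): {trace.i_pA[-1]:.1f} pA (inactivation)")
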