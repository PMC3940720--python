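"""Seconds-scale recovery from C-type inactivation (two-pulse protocol).

P1 (+50 mV, 1 s) drives the channels into the inactivated state, a
variable gap at the recovery voltage lets them recover, and P2 (+50 mV,
150 ms) probes how many are available again.  The P2/P1 peak ratio
versus gap length is fitted with a single exponential with a free
plateau: at -90 mV recovery is complete but slow (~14 s); at -45 mV it
is faster but incomplete, because -45 mV sits near the availability
midpoint so a fraction of channels stays inactivated forever.
"""

import numpy as np

from kv13tcell import (
    ChannelPopulation,
    Kv13Model,
    fractional_recovery,
    recovery_protocol,
    whole_cell_current,
)

model = Kv13Model()
pop = ChannelPopulation(1500)
intervals_ms = np.geomspace(250.0, 60_000.0, 10)

for v_rec in (-90.0, -45.0):
    fam = recovery_protocol(v_rec, intervals_ms)
    sweeps = [whole_cell_current(model.trace(p, 0.1), pop) for p in fam]
    rc = fractional_recovery(sweeps, fam)
    print(f"recovery at {v_rec:+.0f} mV:")
    for t_s, f in zip(rc.intervals_s, rc.fractions):
        print(f"  gap {t_s:7.2f} s   P2/P1 = {f:.3f}")
    print(f"  tau_rec = {rc.tau_s:.1f} s, plateau = {rc.plateau:.2f}\n")
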