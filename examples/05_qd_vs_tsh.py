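"""Surface-hopping swarms against the exact wavepacket.

Propagates (i) the grid wavepacket under the explicit 20 fs pulse,
(ii) a hopping swarm from EOE initial conditions (time-shifted by the
selected start times), and (iii) a swarm from the sudden-scheme window,
then compares the S1 bond-length statistics.  The sudden swarm lacks the
temporal spread of the excitation and comes out too narrow.
"""

import dataclasses

import numpy as np

from eoexcite import eod, nai_model, qdgrid, sampling, select, tsh1d, workflow
from eoexcite.units import BOHR_ANGSTROM, fs_to_au

model = nai_model()
wf = qdgrid.imaginary_time_ground_state(model)
dist = sampling.wigner_distribution(wf, mass=model.reduced_mass)
samples = sampling.draw_samples(dist, 10_000, seed=1)
pulse = workflow.study_pulse("low", 20.0)

table = pulse.sample(fs_to_au(0.1), block=1)
traj = qdgrid.propagate(dataclasses.replace(wf, time=float(table.times[0])),
                        model, table, dt=fs_to_au(0.1),
                        t_end=fs_to_au(700.0), stride=10)
qd = qdgrid.observables(traj, model, "S1")

traces = eod.run_ensemble(samples, model, pulse)
sel_eoe = select.select_initial_conditions(select.renormalize(traces), seed=2)
sw = tsh1d.run_swarm(sel_eoe, samples, model, t_end_fs=700.0, seed=3,
                     max_trajectories=250)
eoe = tsh1d.time_shifted_observables(sw, sel_eoe)

sel_v = select.vertical_select(samples, model, (3.65, 3.71), seed=2)
sw_v = tsh1d.run_swarm(sel_v, samples, model, t_end_fs=700.0, seed=3,
                       max_trajectories=250)
vert = tsh1d.time_shifted_observables(sw_v, sel_v)

t = fs_to_au(np.arange(100.0, 651.0, 10.0))
print("time-averaged S1 statistics, 100-650 fs after the pulse center:")
for name, obs in (("quantum reference", qd), ("EOE swarm", eoe),
                  ("sudden swarm", vert)):
    o = obs.interp(t)
    print(f"  {name:18s} <R> = {np.nanmean(o.r_mean) * BOHR_ANGSTROM:6.3f} A   "
          f"<dR> = {np.nanmean(o.r_std) * BOHR_ANGSTROM:6.3f} A")
print("\nall three agree on the mean bond length; only the EOE swarm also")
print("reproduces the width of the quantum wavepacket, because it spreads")
print("its trajectories over the true distribution of excitation times")
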