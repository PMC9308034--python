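"""Scenario (i): gradual physician removal until one remains.

Physicians of one specialty are removed one at a time, country-wide and
uniformly at random; displaced patients search along the sharing network.
The ensemble yields per-state resilience curves and the critical limits
L_FC (free capacity below 20%) and L_LP (lost patients above 1%).
"""

import carenet as cn

cfg = cn.SynthConfig(seed=1)
municipalities, physicians, contacts = cn.generate_dataset(cfg)
net = cn.threshold_network(
    cn.build_sharing_network(contacts, physicians=physicians),
    p=2, d=100.0, municipalities=municipalities)
layer = cn.specialty_layer(net, "GP")
profiles = cn.build_profiles(contacts, physicians, c=10)
system = cn.compile_system(layer, profiles[profiles["specialty"] == "GP"],
                           municipalities)

params = cn.SimulationParams(seed=7, ensemble_size=20)
trajectories = cn.run_removal_ensemble(system, params)
curves = cn.resilience_curves(trajectories)
limits = cn.critical_limits(curves)

print(f"system: {system.n_physicians} GPs, {system.total_patients} patients, "
      f"{len(trajectories)} replicates")
print("critical limits per state (fraction of GPs removable):")
print(limits.round(3).to_string(index=False))
print("smaller L_LP = patients get lost sooner = less resilient state")
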