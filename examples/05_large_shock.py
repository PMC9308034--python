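"""Scenario (ii): a sudden shock removing 15% of physicians at once.

After the shock, exactly s=10 displacement rounds run; the observable is
the number of patients who currently have an active physician.  Patients
still searching after round 10 are lost.
"""

import numpy as np

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

params = cn.SimulationParams(seed=3)
results = cn.run_shock_ensemble(system, params, shock_fraction=15.0,
                                n_replicates=10)

located = np.stack([r.located for r in results])
total = system.total_patients
print(f"{results[0].n_removed} of {system.n_physicians} GPs removed at once; "
      f"{total} patients in the system")
for t in range(located.shape[1]):
    print(f"round {t:2d}: {located[:, t].mean():7.1f} patients with an "
          f"active physician ({100 * located[:, t].mean() / total:.1f}%)")
lost = np.mean([r.lost[-1] for r in results])
print(f"lost after round {params.s}: {lost:.1f} patients "
      f"({100 * lost / total:.2f}%) — displaced patients the network could "
      "not re-absorb")
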