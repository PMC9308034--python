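"""Estimate capacities and compute per-physician risk/benefit scores.

A physician's maximum capacity C is the median quarterly load of the top
10% busiest physicians in their (specialty, opening-hour bin); the risk
score R_i is the mean clamped load i's neighbours would bear if i's
patients were redistributed along the sharing weights, and the benefit
score B_i is the min-max normalised initial free capacity.
"""

import carenet as cn

cfg = cn.SynthConfig(seed=1)
municipalities, physicians, contacts = cn.generate_dataset(cfg)
net = cn.threshold_network(
    cn.build_sharing_network(contacts, physicians=physicians),
    p=2, d=100.0, municipalities=municipalities)

profiles = cn.build_profiles(contacts, physicians, c=10)
gp = profiles[profiles["specialty"] == "GP"]
print(f"GP quarterly loads N: median {gp['N'].median():.0f}, "
      f"capacities C: median {gp['C'].median():.0f} "
      f"(C >= N for everyone: {(gp['C'] >= gp['N']).all()})")

layer = cn.specialty_layer(net, "GP")
risk = cn.risk_scores(layer, gp)
benefit = cn.benefit_scores(profiles, "GP")
print(f"risk scores:    mean {risk.mean():.3f}, max {risk.max():.3f} "
      "(1 = neighbours would be saturated)")
print(f"benefit scores: span [{benefit.min():.1f}, {benefit.max():.1f}] "
      "(1 = most spare capacity in the specialty)")

states = gp.set_index("physician_id")["municipality_id"].str[0]
levels = cn.regional_levels(risk, states)
print("share of GPs above the nationwide mean risk, by state:")
print(levels.round(1).to_string())
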