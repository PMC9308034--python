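"""Build and threshold a patient-sharing network.

Two physicians are linked by the number of distinct patients who visited
both within a ±91-day window; edges with fewer than p=2 shared patients or
spanning more than d=100 km are pruned, and each medical specialty forms
its own layer.
"""

import carenet as cn

cfg = cn.SynthConfig(seed=1)
municipalities, physicians, contacts = cn.generate_dataset(cfg)

net = cn.build_sharing_network(contacts, window_days=91, physicians=physicians)
print(f"raw network:        {net.number_of_nodes()} physicians, "
      f"{net.number_of_edges()} edges")

net = cn.threshold_network(net, p=2, d=100.0, municipalities=municipalities)
print(f"thresholded (p=2, d=100 km): {net.number_of_edges()} edges")

layer = cn.specialty_layer(net, "GP")
flags = cn.giant_component(layer)
share = sum(flags.values()) / len(flags)
print(f"GP layer:           {layer.number_of_nodes()} physicians, "
      f"{layer.number_of_edges()} edges")
print(f"giant component:    {100 * share:.0f}% of GPs "
      f"(the connected core patients can traverse)")
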