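"""Generate a synthetic year of physician visit records.

Produces the three tables every downstream step consumes: a municipality
gazetteer (5-digit IDs, leading digit = federal state), a physician table
with weekly opening hours, and one year of patient contacts.
"""

import pandas as pd

import carenet as cn

cfg = cn.SynthConfig(seed=1)
municipalities, physicians, contacts = cn.generate_dataset(cfg)

print(f"municipalities: {len(municipalities)} in "
      f"{municipalities['municipality_id'].str[0].nunique()} states")
print(f"physicians:     {len(physicians)} across "
      f"{physicians['specialty'].nunique()} specialties")
print(f"contacts:       {len(contacts)} visits by "
      f"{contacts['patient_id'].nunique()} patients")

loads = contacts["physician_id"].value_counts()
print(f"visits per physician: median {loads.median():.0f}, "
      f"max {loads.max()} (heavy-tailed, like real claims data)")

dates = pd.to_datetime(contacts["date"])
print(f"period: {dates.min().date()} .. {dates.max().date()}")
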