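"""Descriptive statistics of layered egocentric networks.

Computes the mean scaling ratio of published cumulative layer-size
series, the mean and spread of natural human community sizes, and the
cumulative social-effort share reaching the inner 15 alters.
"""

import dunbargraph as dg
from dunbargraph import datasets

for label, fetch in [
    ("personal networks", datasets.personal_network_average),
    ("community structure", datasets.community_structure_average),
    ("multilevel mammals", datasets.multilevel_mammal_layers),
    ("primate groups", datasets.primate_group_sizes),
]:
    scheme = fetch()
    print(f"{label:>20}: sizes {scheme.cumulative_sizes}")
    print(f"{'':>20}  mean scaling ratio = {dg.mean_scaling_ratio(scheme):.2f}")

mean, sd = dg.summarize_group_sizes(datasets.community_size_table())
print(f"\ncommunity sizes: mean = {mean:.1f}, sample sd = {sd:.1f} (n = 12)")

scheme = dg.LayerScheme()  # canonical 5, 15, 50, 150, 500, 1500, 5000
profile = dg.default_effort_profile(scheme)
print(f"effort to inner 5:  {100 * dg.cumulative_effort(profile, scheme, 0):.0f}%")
print(f"effort to inner 15: {100 * dg.cumulative_effort(profile, scheme, 1):.0f}%")
print("\nSuccessive layers are ~3x the size of the one inside them, and")
print("60% of all social time goes to just 15 people.")
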