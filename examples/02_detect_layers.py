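"""Detect layer structure in contact-rate data.

Generates a synthetic ego whose 150 alters fall into layers of
cumulative size 5/15/50/150 with a 3x contact-rate drop per layer, then
recovers the layer count and boundaries by exact natural-breaks
clustering with silhouette selection.
"""

import dunbargraph as dg

config = dg.EgoGeneratorConfig(log10_noise_sd=0.08, rng_seed=7)
table = dg.gen_ego_contacts(config)
fit = dg.detect_layers(table)

print(f"alters: {len(table)}, planted layers: {config.cumulative_sizes}")
print(f"detected k = {fit.k}")
print(f"cumulative layer sizes: {fit.layer_sizes_cumulative}")
print(f"rate thresholds (events/day): {[round(b, 3) for b in fit.breaks]}")
print(f"mean scaling ratio: {fit.mean_scaling_ratio:.2f}")
print("\nThe detector recovers the planted four-layer structure when the")
print("within-layer spread is small relative to the 3x between-layer gaps;")
print("at the generator's default log10 noise (0.3) adjacent layers overlap")
print("too much to be statistically separable from one ego's 150 rates.")
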