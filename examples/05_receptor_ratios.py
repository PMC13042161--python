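"""Receptor-ratio maps, connectome similarity and tau associations.

Builds a 19-marker neurotransmission panel, derives the excitatory/inhibitory
and transmitter-balance ratio maps, correlates them with a tau map, and
compares two connectomes with SSIM / cosine / Pearson similarity.
"""

import numpy as np

import tauspread as ts

n = 40
panel = ts.generate_receptor_panel(n, seed=5)
ratios = ts.receptor_ratio_maps(panel)
print("derived ratio maps:", ", ".join(ratios))

# sanity anchor: on a constant panel the formulas' term counts fix the values
flat = ts.receptor_ratio_maps(ts.generate_receptor_panel(n, seed=0, constant=1.0))
print(f"constant-panel anchors: E:I={flat['E:I'][0]:.2f}, "
      f"R/Re_ACh={flat['R/Re_ACh'][0]:.2f}, NT/NM={flat['NT/NM'][0]:.2f}")

# associate markers and ratios with a synthetic tau map, profiled by stage
spec = ts.SyntheticSpec(n_regions=n, seed=6, epicenter_index=2)
conn = ts.generate_connectome(spec)
table, truth = ts.generate_cohort(spec, conn)
tau_map = ts.group_average_map(ts.minmax_normalize_load(table),
                               table.group_mask("positive"))
stages = ["I", "II", "III", "IV", "V", "VI"]
order = np.argsort(-conn.weights[2])
assignment = {conn.labels[r]: stages[min(k // 7, 5)] for k, r in enumerate(order)}
maps = dict(panel.maps)
maps.update(ratios)
df = ts.ratio_tau_association(maps, tau_map, conn.labels, assignment)
print("\nstrongest tau correlations (|r|):")
for _, row in df.reindex(df.r.abs().sort_values(ascending=False).index).head(3).iterrows():
    print(f"  {row['map']}: r={row.r:+.2f}, stage VI - I change={row.stage_delta:+.2f}")

# connectome similarity: a network against its own surrogate
surrogate = ts.scramble_connectome(conn, seed=1)
ssim, cos, r = ts.connectome_similarity(conn, surrogate)
print(f"\nconnectome vs degree/strength-preserving surrogate: "
      f"SSIM={ssim:.2f}, cosine={cos:.2f}, R={r:.2f}")
print("(rewiring the topology while preserving degrees and strengths "
      "destroys edge-level similarity)")
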