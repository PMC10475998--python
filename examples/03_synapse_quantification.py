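"""Image-based synapse classification and cluster counting.

Runs the full imaging chain on synthetic multi-channel images: segment
each marker channel, classify VGLUT1/VGLUT2 synapses by PSD95 overlap,
then count clusters whose centroids fall inside each compartment.
"""

import nanosyn as ns

config = ns.RunConfig(scene=ns.SceneParams(field_size_um=30, seed=11),
                      n_animals=2, images_per_animal=2, seed=11)
result = ns.run_airyscan_analysis(config)

print(result["report"].stage_counts)
print("\nper-category containment, mean over animals:")
print(result["summary"].to_string(index=False))

df = result["synapses"]
for subtype in ("VGLUT1", "VGLUT2"):
    sub = df[df["subtype"] == subtype]
    density = ns.compute_cluster_density(
        int(sub["n_clusters_presyn"].sum()),
        float(sub["terminal_area_um2"].sum()))
    print(f"{subtype}: {len(sub)} synapses, mean terminal area "
          f"{sub['terminal_area_um2'].mean():.2f} um^2, cluster density "
          f"{density:.2f} / um^2")
# VGLUT1 terminals are larger and more often occupied, but the small,
# abundant VGLUT2 terminals carry the higher cluster density -- the
# area-normalised count inverts the raw-occupancy ranking.
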