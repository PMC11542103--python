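"""Generate one synthetic fundus vasculature and measure its 17 phenotypes.

The generator draws an artery and a vein tree (binary masks) around an optic
disc and records ground truth; the extractor then recovers the phenotypes
from the rasters alone, so truth vs measurement shows the pipeline's
accuracy on a single image.
"""

from retvasc.phenotypes import compute_idps
from retvasc.synthetic import TreeParams, generate_tree

params = TreeParams(depth=3, arcade_sup_deg=55, arcade_inf_deg=55, seed=1)
artery, vein, od, truth = generate_tree(params)
idp = compute_idps(artery, vein, od)

print(f"synthetic image: depth {params.depth} trees, "
      f"OD at {od.center}, radius {od.radius} px")
print(f"{'phenotype':28s} measured   (truth where known)")
for name, value in idp.values.items():
    print(f"{name:28s} {value:8.3f}", end="")
    if name == "bifurcations":
        print(f"   (true {2 * truth.n_bifurcations_per_class})")
    elif name.endswith("temporal_angle"):
        print(f"   (true {truth.true_temporal_angle_deg['artery']:.1f} deg)")
    elif name == "a_tortuosity":
        print(f"   (true median {truth.median_tortuosity('artery'):.4f})")
    else:
        print()
# Angles are degrees at the OD centre; tortuosity is arc/chord (1 = straight);
# diameters and central retinal equivalents are pixels; densities are the
# vessel fraction of the region of interest; ratios are artery/vein.
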