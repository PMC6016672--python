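"""Activity-dependent scaling of dendritic inhibition: compare the calcium
inhibition of a single bAP with that of a bAP preceded (20 ms) by a
5-spike train at 50 or 100 Hz, at control and low A-type density.

The train partially inactivates the A-type channel (the ka_b column),
which enhances inhibition of the following test response; the enhancement
is frequency-dependent and occluded when the A-type density is already
low — the model analogue of 4-AP occlusion.
"""

from kagate import protocols as pro

table = pro.train_scaling_study()     # g in {70, 10}, trains at 50/100 Hz

for g in (70.0, 10.0):
    sub = table[(table["gka"] == g) & (table["site"] == "spine")]
    sub = sub.set_index("condition")
    single = sub.loc["single", "inhibition_fraction"]
    print(f"\ngK_A distal = {g:.0f} mS/cm2")
    for cond in ("single", "train@50Hz", "train@100Hz"):
        row = sub.loc[cond]
        enh = row["inhibition_fraction"] - single
        print(f"  {cond:12s}: inhibition {row['inhibition_fraction']:.3f} "
              f"(enhancement {enh:+.4f}), A-type availability b = "
              f"{row['ka_b_at_test']:.3f}")
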