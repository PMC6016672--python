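"""Generate a synthetic two-photon line-scan population (10 cells, one
spine/shaft pair each, 10 interleaved trials per condition) and run the
experimental analysis chain end to end: dG/R -> dG/Gsat, photoartifact
correction by uncaging-alone subtraction, 100-ms response integrals,
per-cell inhibition fractions, and a paired exact Wilcoxon test between
two conditions.

Condition B halves the inhibited-trial calcium transient (a strong
injected effect), so the paired test should reach a small exact p-value;
rerun with inh_scale_b=1.0 to see a null comparison.
"""

from kagate import protocols as pro
from kagate import synthetic_imaging as si
from kagate.cable_model import ModelSpec

model = ModelSpec()
graph, i_hold, amp_min = pro.calibrate_condition(model)
amp = pro.calibrate_test_stimulus(graph, i_hold, amp_min)
trials = {
    tt: pro.run_trial(pro.ProtocolSpec(tt, model=model),
                      graph=graph, i_hold=i_hold, amp=amp)
    for tt in ("bAP", "IPSP-bAP", "IPSP")
}

result = si.population_study(
    trials, si.ImagingConfig(), n_cells=10, master_seed=1, inh_scale_b=0.5,
)
print(result.table.round(4).to_string(index=False))
for site, test in result.tests.items():
    print(f"{site}: paired exact Wilcoxon W+ = {test.statistic:.1f}, "
          f"p = {test.p_value:.4g} (n = {test.n_used} cells)")
print("\nSmall p: condition B's stronger inhibition is detected across the "
      "paired population despite per-cell amplitude variability and noise.")
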