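"""Run one back-propagating action potential trial, with and without a
preceding GABAergic IPSP, and print the waveform and calcium metrics.

The model is held at -64 mV by an automatically found somatic current; the
test pulse is the smallest 0.5-ms somatic pulse that evokes exactly one
spike (strengthened just enough to survive the IPSP). The IPSP (2 nS
GABA-A conductance on the shaft, 122.5 um from the soma) precedes the
pulse by 15 ms.
"""

from kagate import calcium_analysis as ca
from kagate import protocols as pro
from kagate.cable_model import ModelSpec

model = ModelSpec(gka_distal=70.0)
graph, i_hold, amp_min = pro.calibrate_condition(model)
amp = pro.calibrate_test_stimulus(graph, i_hold, amp_min)
print(f"holding current : {i_hold * 1e3:7.2f} pA")
print(f"test pulse      : {amp:7.2f} nA (0.5 ms)")

trials = {
    tt: pro.run_trial(pro.ProtocolSpec(tt, model=model),
                      graph=graph, i_hold=i_hold, amp=amp)
    for tt in ("bAP", "IPSP-bAP", "IPSP")
}

for tt in ("bAP", "IPSP-bAP"):
    t = trials[tt]
    win = t.traces["spine"].window(t.t_test - 2, t.t_test + 100)
    m = ca.ap_metrics(win)
    print(f"{tt:9s}: spine AP peak {m.peak:7.2f} mV, half-width "
          f"{m.half_width:5.2f} ms, peak I_Ca {m.peak_ica:.3e} uA/cm2")

frac = pro.paired_inhibition_fraction(
    trials["bAP"], trials["IPSP-bAP"], trials["IPSP"], "spine"
)
print(f"spine Ca inhibition fraction: {frac.fraction:.3f} "
      f"(1 = complete suppression of the evoked Ca flux)")
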