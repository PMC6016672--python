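# Default configuration: the simulated layer-5 pyramidal cell and the
# acquisition settings of the synthetic two-photon line-scan stage.

[model]
gka_distal = 70.0      # mS/cm2, distal maximum of the A-type gradient
gna = 4.0              # mS/cm2, uniform
gkdr = 0.1             # mS/cm2, uniform along the dendrite
gkdr_soma = 15.0       # mS/cm2, somatic delayed rectifier
gca = 1e-7             # mS/cm2, reporter Ca channel (spine head + shaft)
cm = 1.0               # uF/cm2
ra = 150.0             # Ohm*cm
gleak = 0.033          # mS/cm2
eleak = -70.0          # mV

[model.synapse]
g_max = 2.0            # nS, peak conductance
tau_rise = 5.0         # ms
tau_decay = 74.0       # ms
reversal = -70.0       # mV (chloride)

[protocol]
dt = 0.005             # ms, implicit Euler step
sweep_grid = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
train_g_values = [70.0, 10.0]
train_freqs = [50.0, 100.0]

[imaging]
kd = 2.3               # uM, indicator dissociation constant
ca_rest = 0.05         # uM
ca_per_flux = 4e5      # uM per (uA*ms/cm2)
decay_tau = 50.0       # ms
g0 = 100.0
gsat = 600.0
red = 200.0
noise_sd = 10.0
line_rate = 500.0      # Hz
n_trials = 10
artifact_amp = 30.0
artifact_tau = 2.0

[run]
n_cells = 10
inh_scale_b = 1.0
seed = 0
out_dir = "kagate_out"
log_level = "INFO"
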