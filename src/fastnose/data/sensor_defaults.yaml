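schema_version: 1
# Synthetic stand-in parameters for the 8-channel MEMS MOx array.  The array
# tiles four base sensor types (two packages of each), with deterministic
# +/-20% multiplicative jitter applied per physical sensor so duplicated
# types are not identical.  Sensitivity profiles are synthetic: the real
# devices' analyte spectra are not published.  Coefficients are scaled
# roughly inversely to each odorant's relative headspace strength so that
# full-concentration responses are comparable across odors.
common:
  beta_per_degc: 0.01       # log-resistance slope vs temperature
  t_ref_degc: 400.0
  alpha: 1.0                # gas power-law exponent
  e_a_kelvin: 1500.0        # adsorption activation scale
  e_d_kelvin: 1800.0        # desorption activation scale
  tau_film_ms: 25.0         # film low-pass
  r_h0_ohm: 30.0            # heater resistance at ambient
  alpha_h_per_degc: 0.003   # heater tempco
  c_th_j_per_degc: 6.383e-07 # hotplate thermal capacity (tau_th ~ 3 ms)
  r_th_degc_per_w: 4700.0   # hotplate thermal resistance (still air)
  r_sense_ohm: 10.0
types:
  - name: ester_tuned
    r_ref_ohm: 150000.0
    k_a0_per_s: 1960.0
    k_d0_per_s: 174.0
    sensitivity: {IA: 3.0, EB: 0.4, Eu: 1.2, "2H": 8.0}
  - name: broadband
    r_ref_ohm: 30000.0
    k_a0_per_s: 2560.0
    k_d0_per_s: 139.0
    sensitivity: {IA: 0.6, EB: 1.8, Eu: 0.9, "2H": 4.0}
  - name: ether_tuned
    r_ref_ohm: 60000.0
    k_a0_per_s: 1370.0
    k_d0_per_s: 209.0
    sensitivity: {IA: 1.5, EB: 0.9, Eu: 4.5, "2H": 12.0}
  - name: ketone_tuned
    r_ref_ohm: 12000.0
    k_a0_per_s: 2160.0
    k_d0_per_s: 157.0
    sensitivity: {IA: 0.8, EB: 0.5, Eu: 2.0, "2H": 20.0}
layout: [0, 1, 2, 3, 0, 1, 2, 3]
jitter_fraction: 0.2
heater_jitter_fraction: 0.02
jitter_seed: 12345
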