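{
  "version": 1,
  "comment": "Phenotype preset table for the synthetic cohort generator. Group means are order-of-magnitude physiological choices for cultured cortical neurons; the Tau group encodes the qualitative tauopathy phenotype (elevated R_m, reduced C_m, depolarized rest, reduced inward/outward voltage-gated currents, reduced spike amplitude, single-spike firing via strong adaptation) and the AR-treated Tau group restores WT-like values with a narrower spike. Per-cell jitter: log-normal (sigma in log space) for positive parameters, additive normal (mV) for voltages.",
  "presets": {
    "WT": {
      "means": {
        "e_leak": -65.0, "r_mem": 150.0, "r_series": 10.0, "c_mem": 100.0,
        "v_threshold": -45.0, "v_reset": -55.0,
        "spike_peak": 30.0, "spike_rise_slope": 150.0, "spike_fall_slope": -50.0,
        "adapt_increment": 20.0, "adapt_tau": 120.0,
        "g_in_scale": 1.0, "g_out_scale": 1.0, "noise_sd": 10.0
      },
      "lognorm_sigma": 0.15, "voltage_sd": 1.5
    },
    "WT_AR": {
      "means": {
        "e_leak": -65.0, "r_mem": 150.0, "r_series": 10.0, "c_mem": 100.0,
        "v_threshold": -45.0, "v_reset": -55.0,
        "spike_peak": 30.0, "spike_rise_slope": 150.0, "spike_fall_slope": -50.0,
        "adapt_increment": 20.0, "adapt_tau": 120.0,
        "g_in_scale": 1.0, "g_out_scale": 1.0, "noise_sd": 10.0
      },
      "lognorm_sigma": 0.15, "voltage_sd": 1.5
    },
    "Tau": {
      "means": {
        "e_leak": -58.0, "r_mem": 250.0, "r_series": 10.0, "c_mem": 60.0,
        "v_threshold": -42.0, "v_reset": -52.0,
        "spike_peak": 20.0, "spike_rise_slope": 150.0, "spike_fall_slope": -50.0,
        "adapt_increment": 120.0, "adapt_tau": 120.0,
        "g_in_scale": 0.45, "g_out_scale": 0.55, "noise_sd": 10.0
      },
      "lognorm_sigma": 0.15, "voltage_sd": 1.5
    },
    "Tau_AR": {
      "means": {
        "e_leak": -64.0, "r_mem": 160.0, "r_series": 10.0, "c_mem": 95.0,
        "v_threshold": -44.0, "v_reset": -55.0,
        "spike_peak": 24.0, "spike_rise_slope": 150.0, "spike_fall_slope": -70.0,
        "adapt_increment": 30.0, "adapt_tau": 120.0,
        "g_in_scale": 0.95, "g_out_scale": 0.95, "noise_sd": 10.0
      },
      "lognorm_sigma": 0.15, "voltage_sd": 1.5
    }
  }
}
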