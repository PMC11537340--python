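{
  "description": "Compartmental relaxation times, volume fractions, D-glucose concentrations per glycemic state, and water densities for brain tissues at 3 T.",
  "version": 1,
  "field_strength_T": 3.0,
  "hydroxyl_pools": {
    "shifts_ppm": [0.66, 1.28, 2.08, 2.88],
    "protons_per_glucose": [1.0, 3.0, 0.36, 0.64],
    "exchange_rates_hz": {
      "normal": [2900.0, 6500.0, 5200.0, 14300.0],
      "tumor_acidic": [1500.0, 3100.0, 2500.0, 6000.0]
    },
    "T1_s": 1.2,
    "T2_s": 0.1
  },
  "water_proton_concentration_mM": 111000.0,
  "compartments": {
    "arterial": {
      "T1_s": 1.91, "T2_s": 0.152, "water_density": 0.856,
      "glucose_mM": {"normoglycemia": 6.15, "hyperglycemia": 19.8},
      "pH_regime": "normal"
    },
    "venous": {
      "T1_s": 1.73, "T2_s": 0.052, "water_density": 0.856,
      "glucose_mM": {"normoglycemia": 5.47, "hyperglycemia": 19.1},
      "pH_regime": "normal"
    },
    "EES_GM": {
      "T1_s": 3.48, "T2_s": 2.78, "water_density": 0.938,
      "glucose_mM": {"normoglycemia": 2.24, "hyperglycemia": 6.10},
      "pH_regime": "normal"
    },
    "EES_WM": {
      "T1_s": 3.48, "T2_s": 2.78, "water_density": 0.938,
      "glucose_mM": {"normoglycemia": 2.42, "hyperglycemia": 5.71},
      "pH_regime": "normal"
    },
    "EES_TUMOR": {
      "T1_s": 3.48, "T2_s": 2.78, "water_density": 0.938,
      "glucose_mM": {"normoglycemia": 5.45, "hyperglycemia": 17.6},
      "pH_regime": "tumor_acidic"
    },
    "EES_CSF": {
      "T1_s": 3.48, "T2_s": 2.78, "water_density": 0.938,
      "glucose_mM": {"normoglycemia": 3.69, "hyperglycemia": 11.9},
      "pH_regime": "normal"
    },
    "cell_GM": {
      "T1_s": 1.08, "T2_s": 0.071, "water_density": 0.809,
      "glucose_mM": {"normoglycemia": 0.167, "hyperglycemia": 1.16},
      "pH_regime": "normal"
    },
    "cell_WM": {
      "T1_s": 0.65, "T2_s": 0.055, "water_density": 0.678,
      "glucose_mM": {"normoglycemia": 0.381, "hyperglycemia": 1.24},
      "pH_regime": "normal"
    },
    "cell_TUMOR": {
      "T1_s": 1.02, "T2_s": 0.071, "water_density": 0.674,
      "glucose_mM": {"normoglycemia": 0.811, "hyperglycemia": 4.41},
      "pH_regime": "normal"
    }
  },
  "tissues": {
    "blood": {
      "blood_fraction": 1.0, "EES_fraction": 0.0, "cell_fraction": 0.0,
      "arterial_subfraction": 0.3, "venous_subfraction": 0.7,
      "EES_compartment": null, "cell_compartment": null,
      "tissue_water_density": 0.856
    },
    "arterial": {
      "blood_fraction": 1.0, "EES_fraction": 0.0, "cell_fraction": 0.0,
      "arterial_subfraction": 1.0, "venous_subfraction": 0.0,
      "EES_compartment": null, "cell_compartment": null,
      "tissue_water_density": 0.856
    },
    "venous": {
      "blood_fraction": 1.0, "EES_fraction": 0.0, "cell_fraction": 0.0,
      "arterial_subfraction": 0.0, "venous_subfraction": 1.0,
      "EES_compartment": null, "cell_compartment": null,
      "tissue_water_density": 0.856
    },
    "GM": {
      "blood_fraction": 0.038, "EES_fraction": 0.22, "cell_fraction": 0.742,
      "arterial_subfraction": 0.3, "venous_subfraction": 0.7,
      "EES_compartment": "EES_GM", "cell_compartment": "cell_GM",
      "tissue_water_density": 0.839
    },
    "WM": {
      "blood_fraction": 0.018, "EES_fraction": 0.22, "cell_fraction": 0.762,
      "arterial_subfraction": 0.3, "venous_subfraction": 0.7,
      "EES_compartment": "EES_WM", "cell_compartment": "cell_WM",
      "tissue_water_density": 0.738
    },
    "TUMOR": {
      "blood_fraction": 0.05, "EES_fraction": 0.50, "cell_fraction": 0.45,
      "arterial_subfraction": 0.3, "venous_subfraction": 0.7,
      "EES_compartment": "EES_TUMOR", "cell_compartment": "cell_TUMOR",
      "tissue_water_density": 0.815
    },
    "CSF": {
      "blood_fraction": 0.0, "EES_fraction": 1.0, "cell_fraction": 0.0,
      "arterial_subfraction": 0.3, "venous_subfraction": 0.7,
      "EES_compartment": "EES_CSF", "cell_compartment": null,
      "tissue_water_density": 0.938
    }
  },
  "reference_simulation_results": {
    "baseline_lw_hz": {
      "blood": 87.0, "arterial": 57.0, "venous": 96.0,
      "GM": 65.0, "WM": 60.0, "TUMOR": 42.0, "CSF": 16.0
    },
    "delta_lw_percent": {
      "blood": 0.56, "arterial": 1.3, "venous": 0.30,
      "GM": 0.29, "WM": 0.34, "TUMOR": 7.5, "CSF": 13.0
    }
  }
}
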