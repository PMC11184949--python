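{
  "yield_mean": {
    "response": "yield",
    "provenance": "paper_eq1",
    "intercept": -4.934,
    "predictors": {
      "FM_JS": 4.421, "FM_FS": -3.915, "FM_LFS": 2.537,
      "LM_JS": 1.081, "LM_FS": 1.808, "LM_LFS": 0.399,
      "SM_JS": -0.067, "SM_FS": -0.058, "SM_LFS": -0.025,
      "PM_JS": 0.297, "PM_FS": -2.012, "PM_LFS": 1.681
    }
  },
  "biomass_mean": {
    "response": "biomass",
    "provenance": "paper_eq2",
    "intercept": -8.566,
    "predictors": {
      "FM_JS": 8.575, "FM_FS": -8.184, "FM_LFS": 4.411,
      "LM_JS": 2.594, "LM_FS": 3.819, "LM_LFS": 1.195,
      "SM_JS": -0.127, "SM_FS": -0.182, "SM_LFS": -0.063,
      "PM_JS": -2.572, "PM_FS": 2.145, "PM_LFS": 0.371
    }
  },
  "yield_index": {
    "response": "yield",
    "provenance": "paper_eq3",
    "intercept": 6.621,
    "predictors": {
      "FE_JS": -0.290, "FE_FS": -1.193, "FE_LFS": -1.561,
      "LJ_JS": -1.960, "LJ_FS": -2.559, "LJ_LFS": -1.662,
      "SJ_JS": 3.085, "SJ_FS": -2.517, "SJ_LFS": 4.700,
      "PM_JS": -0.038, "PM_FS": -1.418, "PM_LFS": 1.411
    }
  },
  "biomass_index": {
    "response": "biomass",
    "provenance": "paper_eq4",
    "intercept": 13.609,
    "predictors": {
      "FE_JS": -0.261, "FE_FS": -0.688, "FE_LFS": -3.295,
      "LJ_JS": -7.823, "LJ_FS": -7.212, "LJ_LFS": -3.282,
      "SJ_JS": 13.550, "SJ_FS": 0.654, "SJ_LFS": 0.125,
      "PM_JS": -2.570, "PM_FS": 1.866, "PM_LFS": 0.605
    }
  }
}
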