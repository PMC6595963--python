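{
  "_comment": "Region-index sets for the four reported significance-based selections. 'anterior' lists transcribe the anterior enumerations given in the source results; the non-anterior remainder of each set was never enumerated, so 'completion_synthetic' holds synthetic stand-in members chosen to satisfy the reported totals and DMN splits. Indices are 1-based AAL-90.",
  "dynamic": {
    "NC": {
      "n_reported": 24,
      "anterior": [5, 6, 9, 10, 11, 19, 21, 23, 24, 26, 29, 33, 34, 57, 59, 61, 62, 69, 70],
      "completion_synthetic": [37, 47, 49, 55, 81]
    },
    "SCD": {
      "n_reported": 23,
      "anterior": [10, 15, 17, 19, 20, 21, 63, 65, 66, 70],
      "completion_synthetic": [35, 36, 37, 38, 43, 44, 47, 48, 49, 56, 82, 85, 86]
    }
  },
  "static": {
    "NC": {
      "n_reported": 17,
      "anterior": [5, 6, 11, 15, 16, 21, 28, 34, 57, 67],
      "completion_synthetic": [35, 37, 43, 47, 55, 81, 85]
    },
    "SCD": {
      "n_reported": 23,
      "anterior": [3, 4, 13, 15, 17, 28, 60, 62, 68],
      "completion_synthetic": [36, 38, 40, 44, 47, 48, 49, 50, 55, 56, 81, 82, 85, 86]
    }
  }
}
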