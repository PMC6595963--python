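{
  "_comment": "Group summary statistics (mean, sd) for the NC (n=53) and SCD (n=40) cohorts, with the reported two-tailed p-value for each between-group comparison.",
  "n": {"NC": 53, "SCD": 40},
  "gender_m_f": {"NC": [21, 32], "SCD": [16, 24]},
  "rows": {
    "age": {"NC": [63.50, 8.25], "SCD": [64.90, 8.31], "p_reported": 0.421},
    "education": {"NC": [10.98, 5.10], "SCD": [11.65, 4.53], "p_reported": 0.513},
    "AVLT-I": {"NC": [9.23, 1.89], "SCD": [8.32, 1.92], "p_reported": 0.027},
    "AVLT-D": {"NC": [10.15, 2.87], "SCD": [8.95, 2.66], "p_reported": 0.043},
    "AVLT-R": {"NC": [12.00, 2.61], "SCD": [11.18, 2.75], "p_reported": 0.144},
    "MMSE": {"NC": [28.19, 2.17], "SCD": [28.05, 1.93], "p_reported": 0.750},
    "MoCA": {"NC": [26.22, 3.16], "SCD": [25.51, 1.73], "p_reported": 0.288},
    "CDT": {"NC": [2.64, 0.65], "SCD": [2.57, 0.69], "p_reported": 0.604},
    "CDR": {"NC": [0.00, 0.00], "SCD": [0.01, 0.08], "p_reported": 0.324},
    "CES-DS": {"NC": [2.18, 4.59], "SCD": [4.52, 5.59], "p_reported": 0.073},
    "HIS": {"NC": [0.06, 0.32], "SCD": [0.62, 1.72], "p_reported": 0.058},
    "ADL": {"NC": [20.02, 0.14], "SCD": [20.28, 1.26], "p_reported": 0.228}
  }
}
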