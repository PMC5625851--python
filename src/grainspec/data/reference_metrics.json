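{
  "description": "Published validation-set summary metrics from the single-kernel wheat HSI protein study this package models: per-pretreatment RMSEP (% protein) and validation R2, plus the validation-set reference SD. Used only for internal-consistency (metric identity) checks; the underlying kernel dataset is not deposited.",
  "validation_sd_protein": 2.06,
  "rows": [
    {"pretreatment": "raw", "rmsep": 1.005, "r2_val": 0.762, "asserted": true},
    {"pretreatment": "normalisation", "rmsep": 0.990, "r2_val": 0.768, "asserted": false},
    {"pretreatment": "msc", "rmsep": 0.968, "r2_val": 0.779, "asserted": true},
    {"pretreatment": "snv", "rmsep": 0.973, "r2_val": 0.777, "asserted": true},
    {"pretreatment": "snv+1st_derivative", "rmsep": 0.944, "r2_val": 0.790, "asserted": true},
    {"pretreatment": "snv+detrend", "rmsep": 0.983, "r2_val": 0.772, "asserted": true},
    {"pretreatment": "2nd_derivative", "rmsep": 1.075, "r2_val": 0.728, "asserted": false}
  ],
  "note": "The 'normalisation' row reproduces 0.769 from the identity 1-(RMSEP/SD)^2, off the printed 0.768 in the third decimal (printed-precision rounding); it is reported but not asserted. The '2nd_derivative' row reproduces exactly but the five asserted cells were fixed in advance."
}
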