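{
 "table1_disposition.csv": {
  "description": "Drug-specific model parameters: fitted 3-compartment IV disposition,",
  "sha256": "431d56bf30ec045b20b9caa6203bf419dffe80a37cb8cdf1c1b79e0f1eeca847"
 },
 "table2_solution_pk.csv": {
  "description": "Oral-solution doses: observed clinical summary metrics (literature-reported",
  "sha256": "8da480e5f16b54c98f7d06f579e5d7b095fc40e6e7a6cbb9d72c70c91da89d25"
 },
 "table3_tablet_pk.csv": {
  "description": "IR tablets, two independent clinical studies: observed means vs",
  "sha256": "6561cafb28fcf85482ec593c5068e928286b1a885addfa876bb971aa31d95b04"
 },
 "table4_be_study.csv": {
  "description": "Bioequivalence study of two 5 mg wet-granulation tablets (50 um reference,",
  "sha256": "bced5844ffe28c3acae2528a8fb183dc954276eb1b9e80b9c7cdf51defcfac47"
 },
 "table5_ratios.csv": {
  "description": "Simulated 5 mg mean-profile T/R ratios versus the oral solution (R1) and",
  "sha256": "178aa3ca664e2494b63c1ffec8e1e68ba62329f4490a39c46e9315da9753b14d"
 }
}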