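# Demo: simulate a small FAERS-like database with two planted signals and
# run the full signal-detection flow on it.
seed: 1
drug: ustekinumab
indication_pts: ["Crohn's disease"]
window: {start: 2016Q4, end: 2023Q4}
dictionary: null     # null -> packaged toy PT->SOC table
synonyms: null       # null -> packaged synonym table
input:
  simulate:
    n_cohort: 2000
    n_background: 20000
    duplicate_rate: 0.10
    planted:
      - ["Abscess", 10.0]
      - ["Intestinal obstruction", 6.0]
thresholds: {}       # defaults: a>=3, ROR>=3 & lo>1, PRR>=2 & lo>1, IC025>0, EB05>2
ebgm_percentile: 0.05
rank_by: n_reports
top: 30
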