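# Reference pipeline configuration: a full synthetic run at study scale
# (7 incubation runs, 7 low/high pairs) plus the stoichiometric worked
# examples echoed into the report.
out_dir: rumeth_out
herd:
  seed: 1
  n_pairs: 7
invitro:
  seed: 2
  runs: 7
community:
  seed: 3
  metric: bray_curtis
  permutations: 9999
  min_reads: 30
  min_samples: 3
rumen:
  residence_ne: 20.0
  residence_e: 30.0
  horizon: 48.0
  step: 0.2
reference_profiles:
  - {label: pre-incubation low emitters, acetate: 677, propionate: 156, butyrate: 132}
  - {label: pre-incubation high emitters, acetate: 688, propionate: 158, butyrate: 138}
  - {label: low x grass silage, acetate: 589, propionate: 266, butyrate: 85.6}
  - {label: low x mixed diet, acetate: 541, propionate: 293, butyrate: 109}
  - {label: low x without additive, acetate: 591, propionate: 245, butyrate: 102}
  - {label: low x with additive, acetate: 540, propionate: 314, butyrate: 92.1}
  - {label: high x without additive, acetate: 598, propionate: 246, butyrate: 97.5}
  - {label: high x with additive, acetate: 503, propionate: 355, butyrate: 87.8}
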