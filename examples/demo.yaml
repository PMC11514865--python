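# End-to-end demo: synthetic 2,000-person cohort, quarter-year chain step.
# Run with:  healthexpect all --config examples/demo.yaml --seed 1 --outdir out
seed: 1
indicator: adl          # adl | srh
step: 0.25              # chain step in years
covariates: [lonely, female]
ages: [65, 70, 75, 80, 85, 90, 95, 99]
ci_ages: [65, 75, 85]
draws: 300              # parametric-bootstrap draws for CIs and SEs
cohort:
  synthetic:
    n: 2000
outdir: out
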