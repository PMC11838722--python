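# Demo pipeline: synthetic nine-trait cognitive battery plus one external
# disorder trait, simulated with known architecture and run end to end.
seed: 1
outdir: demo_out
m: 20000
stages: [simulate, munge, ldsc, fit, gwas, clump, correlate]
gwas_target: Gc_u
external:
  label: SCZ
  h2: 0.225
  n: 8000
  factor_corr: [-0.20, -0.25, 0.15, 0.12]
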