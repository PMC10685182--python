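# Demo study: two subpopulations diverged at F = 0.01 from a common
# ancestral frequency vector; the cognate cohort mirrors a mostly-male
# forensic collection, the non-cognate population plays the large
# reference database.
seed: 7
outdir: out
simulation:
  n_autosomal_loci: 10
  n_x_loci: 6
  fst: 0.01
  panel_seed: 2023
  populations:
    cognate: {male: 120, female: 60}
    noncognate: {male: 300, female: 300}
hwe:
  mc_samples: 5000
ld:
  permutations: 300
fst:
  permutations: 500
audit:
  f_values: [0.0, 0.0016, 0.0108, 0.0170]
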