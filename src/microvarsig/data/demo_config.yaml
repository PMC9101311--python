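# Demo pipeline config: the library defaults already encode the emulated
# study conditions (5-FU n=7 / 5-FU+Oxi n=13 / Oxi n=17 subjects sampled at
# day 0 and day 30; transversion weight x1.5 after Oxi and x0.7 after 5-FU;
# mostly-purifying KO families with two planted at omega = 5; 6 genomes in
# 3 planted ANI clusters).  Any field of microvarsig.simulate.SimConfig can
# be overridden under `sim`, and any analysis threshold under
# `study_defaults` (ani_threshold, min_af, min_support, sv_min_support,
# min_snps_per_genome, min_depth, alpha).
sim:
  seed: 0
study_defaults: {}
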