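# Synthetic cohort spec for `dera synth`.
#
# Generates a 30-gene / 50-edge signed network, 10 reference (control)
# samples and one 40-sample tumor group on the log2 scale. The
# `auto_planted` block lets the generator choose unambiguous edges itself:
# 5 shared signal instances planted at 70% prevalence (recoverable at
# T = 0.5) and 5 decoys at 20% (below threshold). Replace `auto_planted`
# with an explicit `planted:` list (source/target/effect/source_state/
# group/prevalence per entry) to pin specific network edges.
seed: 7
n_genes: 30
n_edges: 50
inhibition_fraction: 0.3
n_reference: 10
effect_size_log2: 2.0
noise_sd_log2: 0.3
groups:
  - label: TUMOR
    n_samples: 40
auto_planted:
  n_shared_signal: 5
  signal_prevalence: 0.7
  n_shared_decoys: 5
  decoy_prevalence: 0.2
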