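# Small synthetic end-to-end study (runs in ~10 s).
seed: 1
out_dir: study_out
alpha: 0.05
simulate:
  n_nodes: 40
  n_msni: 10
  n_msci: 31
  seed: 1
# measure parameters
idleness: 0.5
ground_metric: hop
n_null: 20          # rewired surrogates for small-worldness
swap_factor: 10
# expected one-tailed direction of each global measure (MSNI = non-impaired).
# Path-length-style measures have no safe default and must be stated:
# here "robust" is taken to mean shorter paths, so MSCI is expected greater.
global_directions:
  characteristic_path_length: msci_greater
  diameter: msci_greater
correct_correlations: false
combined_family: false
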