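# Demo family: three pockets sharing a perturbed 8-residue core within
# ~5 A of the ligand, each with 4 private outer residues. Used by the
# worked example in the README and by the reproducibility checks.
core:
  n_residues: 8
  radius_band: [3.5, 4.8]
  seed: 11
private:
  n_residues: 4
  radius_band: [6.5, 8.5]
  seed: 23
perturb:
  sigma: 0.3
  seed: 5
n_sites: 3
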