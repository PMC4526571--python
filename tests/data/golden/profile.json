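{
  "labels": [
    "site0",
    "site1"
  ],
  "points": [
    {
      "cutoff": 3.5,
      "n_res_a": 5,
      "n_res_b": 7,
      "score": 0.2962962962962963,
      "similar": false
    },
    {
      "cutoff": 4.0,
      "n_res_a": 7,
      "n_res_b": 7,
      "score": 0.5502645502645502,
      "similar": true
    },
    {
      "cutoff": 4.5,
      "n_res_a": 8,
      "n_res_b": 8,
      "score": 0.6428571428571429,
      "similar": true
    },
    {
      "cutoff": 5.0,
      "n_res_a": 8,
      "n_res_b": 9,
      "score": 0.5339506172839507,
      "similar": true
    },
    {
      "cutoff": 5.5,
      "n_res_a": 8,
      "n_res_b": 10,
      "score": 0.4444444444444444,
      "similar": false
    },
    {
      "cutoff": 6.0,
      "n_res_a": 8,
      "n_res_b": 11,
      "score": 0.38585858585858585,
      "similar": false
    },
    {
      "cutoff": 6.5,
      "n_res_a": 9,
      "n_res_b": 11,
      "score": 0.4121212121212121,
      "similar": false
    },
    {
      "cutoff": 7.0,
      "n_res_a": 11,
      "n_res_b": 12,
      "score": 0.4158249158249158,
      "similar": false
    },
    {
      "cutoff": 7.5,
      "n_res_a": 11,
      "n_res_b": 12,
      "score": 0.4158249158249158,
      "similar": false
    },
    {
      "cutoff": 8.0,
      "n_res_a": 12,
      "n_res_b": 12,
      "score": 0.4225589225589226,
      "similar": false
    }
  ],
  "provenance": [
    "pocketsim v0.1.0",
    "params: lig_a=SBX lig_b=SBX max=8.0 min=3.5 step=0.5 threshold=0.5 tol=0.5",
    "input pdb_a: site0.pdb sha256:e20e748e2bd1af46",
    "input pdb_b: site1.pdb sha256:8ac9fb45c6070aa3"
  ],
  "threshold": 0.5,
  "tolerance": 0.5
}
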