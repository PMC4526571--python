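{
  "core_res_seqs": [
    1,
    2,
    3,
    4,
    5,
    6,
    7,
    8
  ],
  "core_size": 8,
  "n_sites": 3,
  "sites": [
    {
      "core_res_seqs": [
        1,
        2,
        3,
        4,
        5,
        6,
        7,
        8
      ],
      "label": "site0",
      "private_res_seqs": [
        101,
        102,
        103,
        104
      ]
    },
    {
      "core_res_seqs": [
        1,
        2,
        3,
        4,
        5,
        6,
        7,
        8
      ],
      "label": "site1",
      "private_res_seqs": [
        101,
        102,
        103,
        104
      ]
    },
    {
      "core_res_seqs": [
        1,
        2,
        3,
        4,
        5,
        6,
        7,
        8
      ],
      "label": "site2",
      "private_res_seqs": [
        101,
        102,
        103,
        104
      ]
    }
  ]
}
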