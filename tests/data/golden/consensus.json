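{
  "merged": [
    {
      "coord": [
        7.198702009080936,
        -1.2904493798669847,
        -1.8406276570747198
      ],
      "members": [
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "positive",
      "prop": "ALIPHATIC"
    },
    {
      "coord": [
        9.621954309289956,
        0.38310241995835076,
        -1.2927922631724449
      ],
      "members": [
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            1,
            "LYS"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "positive",
      "prop": "DONOR"
    },
    {
      "coord": [
        4.3830382074833105,
        -5.24158006867959,
        -3.036181735072578
      ],
      "members": [
        {
          "residue": [
            "A",
            2,
            "GLU"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            2,
            "GLU"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            2,
            "GLU"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "negative",
      "prop": "ACCEPTOR"
    },
    {
      "coord": [
        2.8627646024179434,
        3.692567268280484,
        2.366090486052246
      ],
      "members": [
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "positive",
      "prop": "ALIPHATIC"
    },
    {
      "coord": [
        4.961218423507876,
        1.9209698195400058,
        3.338258507624888
      ],
      "members": [
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            3,
            "LYS"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "positive",
      "prop": "DONOR"
    },
    {
      "coord": [
        -0.4980721063449603,
        4.511322231025335,
        -3.0746160998141696
      ],
      "members": [
        {
          "residue": [
            "A",
            4,
            "SER"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            4,
            "SER"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            4,
            "SER"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "polar",
      "prop": "DONOR_ACCEPTOR"
    },
    {
      "coord": [
        2.7251858400587623,
        -3.6174421371146117,
        2.2841684866141634
      ],
      "members": [
        {
          "residue": [
            "A",
            5,
            "GLY"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            5,
            "GLY"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            5,
            "GLY"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "non-polar",
      "prop": "ALIPHATIC"
    },
    {
      "coord": [
        -0.15775325572025853,
        4.423544605132817,
        3.9942116354818986
      ],
      "members": [
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "polar",
      "prop": "DONOR"
    },
    {
      "coord": [
        -0.5605688675750325,
        1.961610805998597,
        3.3324087331595535
      ],
      "members": [
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            7,
            "ASN"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "polar",
      "prop": "ACCEPTOR"
    },
    {
      "coord": [
        -1.1930449215546672,
        -0.16408262655042313,
        6.353752539261875
      ],
      "members": [
        {
          "residue": [
            "A",
            8,
            "ASP"
          ],
          "site": "site0"
        },
        {
          "residue": [
            "A",
            8,
            "ASP"
          ],
          "site": "site1"
        },
        {
          "residue": [
            "A",
            8,
            "ASP"
          ],
          "site": "site2"
        }
      ],
      "physchem_class": "negative",
      "prop": "ACCEPTOR"
    }
  ],
  "n_sites": 3,
  "preserved": [],
  "provenance": [
    "pocketsim v0.1.0",
    "params: cutoff=4.0 epsilon=3.0 merge_level=pseudocenter",
    "input pdb0: site0.pdb sha256:e20e748e2bd1af46",
    "input pdb1: site1.pdb sha256:8ac9fb45c6070aa3",
    "input pdb2: site2.pdb sha256:93ff622bbdffcc17"
  ]
}
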