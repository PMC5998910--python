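{
  "name": "heat_shock_response",
  "places": [
    {
      "id": "hsf",
      "initial": 0.67
    },
    {
      "id": "hsf2",
      "initial": 0.00087
    },
    {
      "id": "hsf3",
      "initial": 0.00012
    },
    {
      "id": "hse",
      "initial": 29.73
    },
    {
      "id": "hsf3_hse",
      "initial": 2.96
    },
    {
      "id": "hsp",
      "initial": 766.88
    },
    {
      "id": "hsp_hsf",
      "initial": 1403.13
    },
    {
      "id": "mfp",
      "initial": 517.352
    },
    {
      "id": "hsp_mfp",
      "initial": 71.65
    },
    {
      "id": "prot",
      "initial": 115000000.0
    }
  ],
  "parameters": {
    "k1p": 3.49,
    "k1m": 0.19,
    "k2p": 1.07,
    "k2m": 1e-09,
    "k3p": 0.17,
    "k3m": 1.21e-06,
    "k4": 0.0083,
    "k5p": 9.74,
    "k5m": 3.56,
    "k6": 2.33,
    "k7": 4.31e-05,
    "k8": [
      2.457e-07,
      2.73e-07,
      3.003e-07
    ],
    "k9": 3.2e-05,
    "k11p": 0.00332,
    "k11m": 4.44,
    "k12": 13.94,
    "T": [
      41.8,
      42.0,
      42.2
    ]
  },
  "transitions": [
    {
      "id": "r1",
      "rate": {
        "constant": "k1p"
      }
    },
    {
      "id": "r2",
      "rate": {
        "constant": "k1m"
      }
    },
    {
      "id": "r3",
      "rate": {
        "constant": "k2p"
      }
    },
    {
      "id": "r4",
      "rate": {
        "constant": "k2m"
      }
    },
    {
      "id": "r5",
      "rate": {
        "constant": "k3p"
      }
    },
    {
      "id": "r6",
      "rate": {
        "constant": "k3m"
      }
    },
    {
      "id": "r7",
      "rate": {
        "constant": "k4"
      }
    },
    {
      "id": "r8",
      "rate": {
        "constant": "k5p"
      }
    },
    {
      "id": "r9",
      "rate": {
        "constant": "k5m"
      }
    },
    {
      "id": "r10",
      "rate": {
        "constant": "k6"
      }
    },
    {
      "id": "r11",
      "rate": {
        "constant": "k7"
      }
    },
    {
      "id": "r12",
      "rate": {
        "constant": "k8"
      }
    },
    {
      "id": "r13",
      "rate": {
        "constant": "k9"
      }
    },
    {
      "id": "r14",
      "rate": {
        "constant": "k10",
        "expression": "(1 - 0.4/exp(T - 37)) * 1.4**(T - 37) * 1.45e-5"
      }
    },
    {
      "id": "r15",
      "rate": {
        "constant": "k11p"
      }
    },
    {
      "id": "r16",
      "rate": {
        "constant": "k11m"
      }
    },
    {
      "id": "r17",
      "rate": {
        "constant": "k12"
      }
    }
  ],
  "arcs": [
    {
      "from": "hsf",
      "to": "r1",
      "weight": 2.0
    },
    {
      "from": "r1",
      "to": "hsf2",
      "weight": 1.0
    },
    {
      "from": "hsf2",
      "to": "r2",
      "weight": 1.0
    },
    {
      "from": "r2",
      "to": "hsf",
      "weight": 2.0
    },
    {
      "from": "hsf",
      "to": "r3",
      "weight": 1.0
    },
    {
      "from": "hsf2",
      "to": "r3",
      "weight": 1.0
    },
    {
      "from": "r3",
      "to": "hsf3",
      "weight": 1.0
    },
    {
      "from": "hsf3",
      "to": "r4",
      "weight": 1.0
    },
    {
      "from": "r4",
      "to": "hsf",
      "weight": 1.0
    },
    {
      "from": "r4",
      "to": "hsf2",
      "weight": 1.0
    },
    {
      "from": "hsf3",
      "to": "r5",
      "weight": 1.0
    },
    {
      "from": "hse",
      "to": "r5",
      "weight": 1.0
    },
    {
      "from": "r5",
      "to": "hsf3_hse",
      "weight": 1.0
    },
    {
      "from": "hsf3_hse",
      "to": "r6",
      "weight": 1.0
    },
    {
      "from": "r6",
      "to": "hsf3",
      "weight": 1.0
    },
    {
      "from": "r6",
      "to": "hse",
      "weight": 1.0
    },
    {
      "from": "hsf3_hse",
      "to": "r7",
      "weight": 1.0
    },
    {
      "from": "r7",
      "to": "hsf3_hse",
      "weight": 1.0
    },
    {
      "from": "r7",
      "to": "hsp",
      "weight": 1.0
    },
    {
      "from": "hsp",
      "to": "r8",
      "weight": 1.0
    },
    {
      "from": "hsf",
      "to": "r8",
      "weight": 1.0
    },
    {
      "from": "r8",
      "to": "hsp_hsf",
      "weight": 1.0
    },
    {
      "from": "hsp_hsf",
      "to": "r9",
      "weight": 1.0
    },
    {
      "from": "r9",
      "to": "hsp",
      "weight": 1.0
    },
    {
      "from": "r9",
      "to": "hsf",
      "weight": 1.0
    },
    {
      "from": "hsp",
      "to": "r10",
      "weight": 1.0
    },
    {
      "from": "hsf2",
      "to": "r10",
      "weight": 1.0
    },
    {
      "from": "r10",
      "to": "hsp_hsf",
      "weight": 1.0
    },
    {
      "from": "r10",
      "to": "hsf",
      "weight": 1.0
    },
    {
      "from": "hsp",
      "to": "r11",
      "weight": 1.0
    },
    {
      "from": "hsf3",
      "to": "r11",
      "weight": 1.0
    },
    {
      "from": "r11",
      "to": "hsp_hsf",
      "weight": 1.0
    },
    {
      "from": "r11",
      "to": "hsf",
      "weight": 2.0
    },
    {
      "from": "hsp",
      "to": "r12",
      "weight": 1.0
    },
    {
      "from": "hsf3_hse",
      "to": "r12",
      "weight": 1.0
    },
    {
      "from": "r12",
      "to": "hsp_hsf",
      "weight": 1.0
    },
    {
      "from": "r12",
      "to": "hse",
      "weight": 1.0
    },
    {
      "from": "r12",
      "to": "hsf",
      "weight": 2.0
    },
    {
      "from": "hsp",
      "to": "r13",
      "weight": 1.0
    },
    {
      "from": "prot",
      "to": "r14",
      "weight": 1.0
    },
    {
      "from": "r14",
      "to": "mfp",
      "weight": 1.0
    },
    {
      "from": "hsp",
      "to": "r15",
      "weight": 1.0
    },
    {
      "from": "mfp",
      "to": "r15",
      "weight": 1.0
    },
    {
      "from": "r15",
      "to": "hsp_mfp",
      "weight": 1.0
    },
    {
      "from": "hsp_mfp",
      "to": "r16",
      "weight": 1.0
    },
    {
      "from": "r16",
      "to": "hsp",
      "weight": 1.0
    },
    {
      "from": "r16",
      "to": "mfp",
      "weight": 1.0
    },
    {
      "from": "hsp_mfp",
      "to": "r17",
      "weight": 1.0
    },
    {
      "from": "r17",
      "to": "hsp",
      "weight": 1.0
    },
    {
      "from": "r17",
      "to": "prot",
      "weight": 1.0
    }
  ]
}
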