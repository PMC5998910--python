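{
  "name": "decay_dimerization",
  "places": [
    {
      "id": "S1",
      "initial": 100.0
    },
    {
      "id": "S2",
      "initial": 0.0
    },
    {
      "id": "S3",
      "initial": 0.0
    }
  ],
  "parameters": {
    "theta1": 0.2,
    "theta2": 0.04,
    "theta3": [
      0.45,
      0.5,
      0.55
    ],
    "theta4": [
      4.9,
      5.0,
      5.4
    ]
  },
  "transitions": [
    {
      "id": "r1",
      "rate": {
        "constant": "theta1"
      }
    },
    {
      "id": "r2",
      "rate": {
        "constant": "theta2"
      }
    },
    {
      "id": "r3",
      "rate": {
        "constant": "theta3"
      }
    },
    {
      "id": "r4",
      "rate": {
        "constant": "theta4"
      }
    }
  ],
  "arcs": [
    {
      "from": "S1",
      "to": "r1",
      "weight": 1.0
    },
    {
      "from": "S1",
      "to": "r2",
      "weight": 2.0
    },
    {
      "from": "r2",
      "to": "S2",
      "weight": 1.0
    },
    {
      "from": "S2",
      "to": "r3",
      "weight": 1.0
    },
    {
      "from": "r3",
      "to": "S1",
      "weight": 2.0
    },
    {
      "from": "S2",
      "to": "r4",
      "weight": 1.0
    },
    {
      "from": "r4",
      "to": "S3",
      "weight": 1.0
    }
  ]
}
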