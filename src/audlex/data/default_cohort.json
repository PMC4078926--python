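{
  "n_nr": 54,
  "n_dys": 36,
  "seed": 0,
  "factors": [
    "literacy",
    "pa",
    "vstm",
    "ran",
    "slow_aud",
    "intensity",
    "speech"
  ],
  "latent_corr": [
    [
      1.0,
      0.5,
      0.35,
      0.3,
      0.15,
      0.15,
      0.05
    ],
    [
      0.5,
      1.0,
      0.45,
      0.45,
      0.2,
      0.2,
      0.1
    ],
    [
      0.35,
      0.45,
      1.0,
      0.3,
      0.1,
      0.1,
      0.15
    ],
    [
      0.3,
      0.45,
      0.3,
      1.0,
      0.2,
      0.2,
      0.05
    ],
    [
      0.15,
      0.2,
      0.1,
      0.2,
      1.0,
      0.35,
      0.1
    ],
    [
      0.15,
      0.2,
      0.1,
      0.2,
      0.35,
      1.0,
      0.05
    ],
    [
      0.05,
      0.1,
      0.15,
      0.05,
      0.1,
      0.05,
      1.0
    ]
  ],
  "demographics": {
    "age": {
      "NR": [
        22.0,
        3.0
      ],
      "DYS": [
        21.8,
        4.8
      ]
    },
    "iq": {
      "NR": [
        112.7,
        9.9
      ],
      "DYS": [
        107.0,
        20.7
      ]
    }
  },
  "measures": {
    "reading": {
      "nr_mean": 106.1,
      "nr_sd": 5.8,
      "dys_mean": 91.7,
      "dys_sd": 10.1,
      "higher_is_better": true,
      "factor": "literacy",
      "uniqueness": 0.33,
      "clip": [
        40,
        160
      ]
    },
    "spelling": {
      "nr_mean": 107.6,
      "nr_sd": 6.6,
      "dys_mean": 90.8,
      "dys_sd": 8.8,
      "higher_is_better": true,
      "factor": "literacy",
      "uniqueness": 0.33,
      "clip": [
        40,
        160
      ]
    },
    "spoonerism": {
      "nr_mean": 0.23,
      "nr_sd": 0.08,
      "dys_mean": 0.1,
      "dys_sd": 0.04,
      "higher_is_better": true,
      "factor": "pa",
      "uniqueness": 0.2,
      "clip": [
        0.005,
        null
      ]
    },
    "digit_span": {
      "nr_mean": 12.32,
      "nr_sd": 1.87,
      "dys_mean": 10.78,
      "dys_sd": 2.0,
      "higher_is_better": true,
      "factor": "vstm",
      "uniqueness": 0.45,
      "clip": [
        0,
        16
      ]
    },
    "nonword_recall": {
      "nr_mean": 20.09,
      "nr_sd": 2.25,
      "dys_mean": 17.61,
      "dys_sd": 2.62,
      "higher_is_better": true,
      "factor": "vstm",
      "uniqueness": 0.45,
      "clip": [
        0,
        36
      ]
    },
    "ran_color": {
      "nr_mean": 2.01,
      "nr_sd": 0.33,
      "dys_mean": 1.72,
      "dys_sd": 0.31,
      "higher_is_better": true,
      "factor": "ran",
      "uniqueness": 0.25,
      "clip": [
        0.05,
        null
      ]
    },
    "ran_object": {
      "nr_mean": 1.77,
      "nr_sd": 0.24,
      "dys_mean": 1.5,
      "dys_sd": 0.25,
      "higher_is_better": true,
      "factor": "ran",
      "uniqueness": 0.25,
      "clip": [
        0.05,
        null
      ]
    },
    "fm": {
      "nr_mean": 3.82,
      "nr_sd": 1.38,
      "dys_mean": 4.58,
      "dys_sd": 2.38,
      "higher_is_better": false,
      "factor": "slow_aud",
      "uniqueness": 0.75,
      "clip": [
        0.5,
        100
      ]
    },
    "rt": {
      "nr_mean": 73.07,
      "nr_sd": 47.41,
      "dys_mean": 117.22,
      "dys_sd": 65.94,
      "higher_is_better": false,
      "factor": "slow_aud",
      "uniqueness": 0.75,
      "clip": [
        1.5,
        485
      ]
    },
    "id": {
      "nr_mean": 1.04,
      "nr_sd": 0.54,
      "dys_mean": 1.46,
      "dys_sd": 0.76,
      "higher_is_better": false,
      "factor": "intensity",
      "uniqueness": 0.3,
      "clip": [
        0.05,
        10
      ]
    },
    "hint": {
      "nr_mean": -3.03,
      "nr_sd": 0.93,
      "dys_mean": -3.11,
      "dys_sd": 0.91,
      "higher_is_better": false,
      "factor": "speech",
      "uniqueness": 0.5,
      "clip": null
    },
    "caspa": {
      "nr_mean": -11.06,
      "nr_sd": 0.92,
      "dys_mean": -11.01,
      "dys_sd": 1.02,
      "higher_is_better": false,
      "factor": "speech",
      "uniqueness": 0.5,
      "clip": null
    }
  },
  "deficit_mix": {
    "literacy": {
      "NR": [
        0.475,
        4.0,
        0.5
      ],
      "DYS": [
        0.875,
        4.0,
        0.7
      ]
    },
    "pa": {
      "NR": [
        0.425,
        1.5,
        0.5
      ],
      "DYS": [
        0.725,
        4.0,
        0.5
      ]
    },
    "vstm": {
      "NR": [
        0.25,
        1.5,
        0.5
      ],
      "DYS": [
        0.55,
        4.0,
        0.5
      ]
    },
    "ran": {
      "NR": [
        0.15,
        1.5,
        0.5
      ],
      "DYS": [
        0.0,
        1.0,
        0.5
      ]
    },
    "rt": {
      "NR": [
        0.225,
        4.0,
        0.5
      ],
      "DYS": [
        0.6,
        4.0,
        0.7
      ]
    },
    "fm": {
      "NR": [
        0.3,
        3.0,
        1.0
      ],
      "DYS": [
        0.025,
        3.5,
        0.5
      ]
    },
    "id": {
      "NR": [
        0.175,
        2.5,
        0.5
      ],
      "DYS": [
        0.125,
        4.0,
        0.5
      ]
    },
    "hint": {
      "NR": [
        0.45,
        1.5,
        0.5
      ],
      "DYS": [
        0.175,
        1.0,
        0.5
      ]
    },
    "caspa": {
      "NR": [
        0.15,
        4.0,
        1.0
      ],
      "DYS": [
        0.85,
        4.0,
        0.5
      ]
    }
  },
  "configured_deviance": {
    "Literacy": {
      "NR": 0.0004,
      "DYS": 0.8613
    },
    "PA": {
      "NR": 0.0206,
      "DYS": 0.7217
    },
    "RAN": {
      "NR": 0.0621,
      "DYS": 0.3121
    },
    "VSTM": {
      "NR": 0.0342,
      "DYS": 0.5289
    },
    "fm": {
      "NR": 0.1447,
      "DYS": 0.3088
    },
    "rt": {
      "NR": 0.2201,
      "DYS": 0.5852
    },
    "id": {
      "NR": 0.1492,
      "DYS": 0.2517
    },
    "hint": {
      "NR": 0.0178,
      "DYS": 0.0295
    },
    "caspa": {
      "NR": 0.1629,
      "DYS": 0.1392
    }
  }
}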