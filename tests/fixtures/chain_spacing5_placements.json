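{
  "trees": [
    [
      5,
      5
    ],
    [
      10,
      5
    ],
    [
      15,
      5
    ],
    [
      20,
      5
    ],
    [
      25,
      5
    ]
  ],
  "sources": [
    [
      2,
      5,
      0
    ]
  ],
  "primates": [
    [
      5,
      6
    ],
    [
      10,
      6
    ],
    [
      15,
      6
    ],
    [
      20,
      6
    ],
    [
      25,
      6
    ],
    [
      5,
      7
    ],
    [
      10,
      7
    ],
    [
      15,
      7
    ],
    [
      20,
      7
    ],
    [
      25,
      7
    ],
    [
      5,
      8
    ],
    [
      10,
      8
    ],
    [
      15,
      8
    ],
    [
      20,
      8
    ],
    [
      25,
      8
    ],
    [
      5,
      9
    ],
    [
      10,
      9
    ],
    [
      15,
      9
    ],
    [
      20,
      9
    ],
    [
      25,
      9
    ]
  ],
  "expectation": "no tool ever exceeds the single-hop bound of 4 cells"
}
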