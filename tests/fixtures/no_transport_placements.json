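{
  "trees": [
    [
      30,
      2
    ],
    [
      30,
      6
    ],
    [
      30,
      10
    ],
    [
      30,
      14
    ],
    [
      30,
      18
    ],
    [
      30,
      22
    ],
    [
      30,
      26
    ],
    [
      30,
      30
    ]
  ],
  "sources": [
    [
      2,
      3,
      0
    ],
    [
      2,
      11,
      0
    ],
    [
      2,
      19,
      0
    ],
    [
      2,
      27,
      0
    ]
  ],
  "primates": [
    [
      20,
      1
    ],
    [
      20,
      3
    ],
    [
      20,
      5
    ],
    [
      20,
      7
    ],
    [
      20,
      9
    ],
    [
      20,
      11
    ],
    [
      20,
      13
    ],
    [
      20,
      15
    ],
    [
      20,
      17
    ],
    [
      20,
      19
    ]
  ],
  "expectation": "no tool is ever created; tool-use-location count is 0 throughout"
}
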