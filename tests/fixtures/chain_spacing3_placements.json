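{
  "trees": [
    [
      5,
      5
    ],
    [
      8,
      5
    ],
    [
      11,
      5
    ],
    [
      14,
      5
    ],
    [
      17,
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
      8,
      6
    ],
    [
      11,
      6
    ],
    [
      14,
      6
    ],
    [
      17,
      6
    ],
    [
      5,
      7
    ],
    [
      8,
      7
    ],
    [
      11,
      7
    ],
    [
      14,
      7
    ],
    [
      17,
      7
    ],
    [
      5,
      8
    ],
    [
      8,
      8
    ],
    [
      11,
      8
    ],
    [
      14,
      8
    ],
    [
      17,
      8
    ],
    [
      5,
      9
    ],
    [
      8,
      9
    ],
    [
      11,
      9
    ],
    [
      14,
      9
    ],
    [
      17,
      9
    ]
  ],
  "expectation": "some tool's displacement from its source exceeds 3 cells"
}
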