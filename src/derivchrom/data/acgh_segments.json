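{
  "seq_name": "chr21",
  "chrom_length": 48129895,
  "analyzed_span": [
    1,
    48096110
  ],
  "analyzed_span_note": "end of array probe coverage; the distal-most duplication runs to the last analyzed position, so its distal edge is a span edge, not a copy-number change point",
  "deletions": [
    {
      "interval": [
        18734534,
        19762829
      ],
      "retained": [
        18873605,
        18943066
      ]
    },
    {
      "interval": [
        33640510,
        36370035
      ],
      "retained": null
    },
    {
      "interval": [
        46869870,
        47319181
      ],
      "retained": null
    }
  ],
  "duplications": [
    [
      15562050,
      17771307
    ],
    [
      20894137,
      22614749
    ],
    [
      23199170,
      23294347
    ],
    [
      24460290,
      24726025
    ],
    [
      26039228,
      26376269
    ],
    [
      47916776,
      48096110
    ]
  ],
  "sha256": "a40700418f777cc0fcb33425e91ad61dc4db1ed48c4c583d8b51a86b20020475"
}
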