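# Published default vs optimized response values for the benchmark cases.
# Used as inputs to percent_improvement; not recomputable without the
# original sequencing data and external tools.
case1_assembly:
  tSeq: {criterion: maximize, default: 1835427, optimized: 1864165}
  nSeq: {criterion: minimize, default: 91, optimized: 89}
  N50: {criterion: maximize, default: 28149, optimized: 31847}
case2_scaffolding:
  N50: {criterion: maximize, default: 1141889, optimized: 1905883}
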