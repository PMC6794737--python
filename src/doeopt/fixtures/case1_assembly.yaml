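# De-novo assembly tuning: four assembler parameters, three responses.
design:
  factors:
    KMER:
      type: ordinal
      min: 20
      max: 90
    MIKC:
      type: quantitative
      min: 2
      max: 15
    MIAL:
      type: ordinal
      min: 20
      max: 60
    MIPA:
      type: ordinal
      min: 5
      max: 15
  responses:
    tSeq:
      criterion: maximize
      low_limit: 1830000
      target: 1894157
    nSeq:
      criterion: minimize
      high_limit: 95
      target: 85
    N50:
      criterion: maximize
      low_limit: 28000
      target: 35000
  reduction_factor: 8
  optimization_design: ccf
  shrinkage: 0.9
  model_selection: greedy
pipeline:
  assemble: >-
    doeopt-mock --spec objective.yaml --out results.txt
    --set KMER={{KMER}} --set MIKC={{MIKC}}
    --set MIAL={{MIAL}} --set MIPA={{MIPA}}
execution:
  mode: sequential
  workdir: doeopt_work
  results_file: results.txt
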