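# Variant calling step tuning: four caller parameters, F1 response.
design:
  factors:
    GMQ:
      type: ordinal
      min: 20
      max: 55
    MBQ:
      type: ordinal
      min: 5
      max: 25
    RAS:
      type: ordinal
      min: 5
      max: 25
    SCC:
      type: quantitative
      min: 5
      max: 25
  responses:
    F1:
      criterion: maximize
  reduction_factor: 8
  optimization_design: ccf
  shrinkage: 0.9
  model_selection: greedy
pipeline:
  call: >-
    doeopt-mock --spec objective.yaml --out results.txt
    --set GMQ={{GMQ}} --set MBQ={{MBQ}}
    --set RAS={{RAS}} --set SCC={{SCC}}
execution:
  mode: sequential
  workdir: doeopt_work
  results_file: results.txt
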