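# Long-read scaffolding tuning: four scaffolder parameters, one response.
design:
  factors:
    ALEN:
      type: ordinal
      min: 0
      max: 5000
    GLEN:
      type: ordinal
      min: -3000
      max: 3000
    RRAT:
      type: quantitative
      min: 0.1
      max: 0.7
    IDEN:
      type: ordinal
      min: 30
      max: 90
  responses:
    N50:
      criterion: maximize
  optimization_design: ccf
  shrinkage: 0.9
  model_selection: greedy
pipeline:
  scaffold: >-
    doeopt-mock --spec objective.yaml --out results.txt
    --set ALEN={{ALEN}} --set GLEN={{GLEN}}
    --set RRAT={{RRAT}} --set IDEN={{IDEN}}
execution:
  mode: sequential
  workdir: doeopt_work
  results_file: results.txt
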