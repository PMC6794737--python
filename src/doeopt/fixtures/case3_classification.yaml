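# K-mer read classification tuning: three classifier parameters, F1 response.
design:
  factors:
    MH:
      type: ordinal
      min: 1
      max: 200
    PRES:
      type: ordinal
      min: 10
      max: 18
    FILT:
      type: quantitative
      min: 0
      max: 0.05
  responses:
    F1:
      criterion: maximize
  optimization_design: ccf
  shrinkage: 0.9
  model_selection: greedy
pipeline:
  classify: >-
    doeopt-mock --spec objective.yaml --out results.txt
    --set MH={{MH}} --set PRES={{PRES}} --set FILT={{FILT}}
execution:
  mode: sequential
  workdir: doeopt_work
  results_file: results.txt
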