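# Variant filtering step tuning: four filter cutoffs, F1 response.
design:
  factors:
    QD:
      type: quantitative
      min: 0
      max: 10
    RPRS:
      type: quantitative
      min: -40
      max: 0
    FS:
      type: quantitative
      min: 0
      max: 250
    SOR:
      type: quantitative
      min: 0
      max: 20
  responses:
    F1:
      criterion: maximize
  reduction_factor: 8
  optimization_design: ccf
  shrinkage: 0.9
  model_selection: greedy
pipeline:
  filter: >-
    doeopt-mock --spec objective.yaml --out results.txt
    --set QD={{QD}} --set RPRS={{RPRS}}
    --set FS={{FS}} --set SOR={{SOR}}
execution:
  mode: sequential
  workdir: doeopt_work
  results_file: results.txt
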