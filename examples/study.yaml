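# Study-scale synthetic run: 20 patients + 20 controls, four sources,
# a 1.5-sd patient shift on source 4 and a clinical metric linked to it.
# Usage: sbm run --config examples/study.yaml --seed 1 --out out
simulate:
  enabled: true
preprocessing:
  resample_mm: null   # generated volumes are already at 3 mm
  fwhm_mm: 0.0        # sources are generated smooth
decomposition:
  k: auto             # MDL order selection
  n_runs: 20          # ICASSO repetitions
stats:
  covariates: [age, tiv]
  fdr_q: 0.05
  z_threshold: 3.0
correlation:
  metrics: [PCS, helplessness, magnification, rumination]
  covariates: [age]
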