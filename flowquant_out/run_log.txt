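workflow: track
seed: 0
inputs: ['/tmp/pytest-of-root/pytest-13/test_unreadable_input_reports_0/missing_dir']
parameters:
  fps: 25.0
  um_per_px: 1.0
versions:
  numpy: 2.4.6
  scipy: 1.17.1
  pandas: 2.3.3
  scikit-image: 0.26.0
  scikit-learn: 1.9.0
  python: 3.11.15
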