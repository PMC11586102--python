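detections: data/detections.csv
deployments: data/deployments.csv
sites: data/sites.yaml
site_id: synthetic_complex
mode: repro_condition
window_days: 14
out_dir: artifacts
seed: 42
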