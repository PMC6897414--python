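# Synthetic study-shaped panel: eight stable genes spanning the
# observed baseline range plus one pressure-regulated gene.
genes:
  - {name: g1, baseline: 9.0, noise_sd: 0.15}
  - {name: g2, baseline: 12.0, noise_sd: 0.15}
  - {name: g3, baseline: 15.0, noise_sd: 0.15}
  - {name: g4, baseline: 18.0, noise_sd: 0.15}
  - {name: g5, baseline: 21.0, noise_sd: 0.15}
  - {name: g6, baseline: 24.0, noise_sd: 0.15}
  - {name: g7, baseline: 27.0, noise_sd: 0.15}
  - {name: g8, baseline: 29.0, noise_sd: 0.15}
  - name: reg
    baseline: 23.0
    noise_sd: 0.15
    regulation: {'N-SF:pressure': 1.5, 'OA-SF:pressure': 1.5}
group_sizes:
  'N-SF:control': 5
  'N-SF:pressure': 5
  'OA-SF:control': 5
  'OA-SF:pressure': 5
loading_sd: 0.2
replicates: 3
seed: 42
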