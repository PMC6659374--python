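# Default fit-window plan. Each window is fitted independently; metabolites
# are assigned to a window when their multiplet lines (after +/- mobility)
# fall inside it. TSP is always fitted in its own reference window.
windows:
  - {name: tsp, high_ppm: 0.25, low_ppm: -0.25}
  - {name: bcaa, high_ppm: 1.12, low_ppm: 0.85}
  - {name: methyl, high_ppm: 1.60, low_ppm: 1.15}
  - {name: acetate, high_ppm: 2.05, low_ppm: 1.80}
  - {name: citrate, high_ppm: 2.85, low_ppm: 2.40}
  - {name: creatinine_tmao, high_ppm: 3.40, low_ppm: 2.90}
  - {name: glycine, high_ppm: 3.70, low_ppm: 3.45}
  - {name: hippurate_aliphatic, high_ppm: 4.20, low_ppm: 3.85}
  - {name: glucose, high_ppm: 5.45, low_ppm: 5.05}
  - {name: urea, high_ppm: 6.00, low_ppm: 5.55}
  - {name: aromatic, high_ppm: 8.05, low_ppm: 7.40}
  - {name: formate, high_ppm: 8.60, low_ppm: 8.05}
  - {name: trigonelline, high_ppm: 9.30, low_ppm: 8.95}
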