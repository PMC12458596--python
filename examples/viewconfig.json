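{
  "mark": "sphere",
  "color": {"field": "gene_density", "colormap": "viridis-8"},
  "scale": {"field": "gene_density", "range": [0.2, 0.6]},
  "links": true
}
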