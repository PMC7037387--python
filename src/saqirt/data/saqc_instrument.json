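{
  "name": "SAQ-C",
  "n_categories": 5,
  "domains": [
    {"id": "TC", "label": "Teamwork Climate", "items": ["TC1", "TC2", "TC3", "TC4", "TC5"]},
    {"id": "SC", "label": "Safety Climate", "items": ["SC1", "SC2", "SC3", "SC4", "SC5", "SC6"]},
    {"id": "JS", "label": "Job Satisfaction", "items": ["JS1", "JS2", "JS3", "JS4", "JS5"]},
    {"id": "PM", "label": "Perception of Management", "items": ["PM1", "PM2", "PM3", "PM4", "PM5", "PM6", "PM7", "PM8", "PM9", "PM10"]},
    {"id": "WC", "label": "Working Conditions", "items": ["WC1", "WC2", "WC3", "WC4"]}
  ]
}
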