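{
  "cookie": ["cookie", "cookies", "biscuit", "biscuits"],
  "cookie jar": ["jar"],
  "boy": ["boy", "son", "brother"],
  "girl": ["girl", "daughter", "sister"],
  "woman": ["woman", "mother", "lady", "mom"],
  "stool": ["stool"],
  "plate": ["plate", "plates"],
  "dishcloth": ["dishcloth", "towel", "cloth"],
  "water": ["water"],
  "window": ["window", "windows", "exterior", "outside", "yard"],
  "curtain": ["curtain", "curtains"],
  "dishes": ["dishes", "dish"],
  "sink": ["sink"]
}
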