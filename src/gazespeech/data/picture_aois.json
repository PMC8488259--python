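[
  {"name": "cookie", "polygon": [[660, 320], [760, 320], [760, 390], [660, 390]]},
  {"name": "cookie jar", "polygon": [[640, 150], [820, 150], [820, 300], [640, 300]]},
  {"name": "boy", "polygon": [[500, 300], [640, 300], [640, 700], [500, 700]]},
  {"name": "girl", "polygon": [[330, 380], [470, 380], [470, 700], [330, 700]]},
  {"name": "woman", "polygon": [[1150, 300], [1320, 300], [1320, 800], [1150, 800]]},
  {"name": "stool", "polygon": [[500, 720], [680, 720], [680, 930], [500, 930]]},
  {"name": "plate", "polygon": [[1340, 520], [1450, 520], [1450, 580], [1340, 580]]},
  {"name": "dishcloth", "polygon": [[1330, 420], [1450, 420], [1450, 480], [1330, 480]]},
  {"name": "water", "polygon": [[1000, 560], [1140, 560], [1140, 640], [1000, 640]]},
  {"name": "window", "polygon": [[1500, 200], [1800, 200], [1800, 520], [1500, 520]]},
  {"name": "curtain", "polygon": [[1440, 180], [1498, 180], [1498, 540], [1440, 540]]},
  {"name": "dishes", "polygon": [[1340, 600], [1500, 600], [1500, 680], [1340, 680]]},
  {"name": "sink", "polygon": [[980, 650], [1140, 650], [1140, 760], [980, 760]]}
]
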