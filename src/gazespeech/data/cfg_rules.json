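[
  "ROOT -> S",
  "S -> NP VP",
  "S -> VP",
  "S -> S CC S",
  "NP -> DT NN",
  "NP -> DT JJ NN",
  "NP -> DT NNS",
  "NP -> DT JJ NNS",
  "NP -> JJ NN",
  "NP -> NN",
  "NP -> NNS",
  "NP -> PRP",
  "NP -> EX",
  "NP -> NP PP",
  "NP -> NP CC NP",
  "NP -> NP SBAR",
  "VP -> VB",
  "VP -> VBZ",
  "VP -> VBD",
  "VP -> VB NP",
  "VP -> VBZ NP",
  "VP -> VBD NP",
  "VP -> VBG NP",
  "VP -> VB PP",
  "VP -> VBZ PP",
  "VP -> VBD PP",
  "VP -> VBG PP",
  "VP -> VBZ VP",
  "VP -> VBD VP",
  "VP -> VB NP PP",
  "VP -> MD VP",
  "VP -> VBZ ADJP",
  "VP -> VBD ADJP",
  "VP -> VP CC VP",
  "VP -> VB SBAR",
  "PP -> IN NP",
  "PP -> TO NP",
  "ADJP -> JJ",
  "ADJP -> RB JJ",
  "ADVP -> RB",
  "SBAR -> IN S",
  "SBAR -> WHNP S",
  "SBAR -> WHADVP S",
  "INTJ -> UH"
]
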