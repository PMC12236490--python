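# FUS domain architecture (1-based inclusive residue ranges, UniProt P35637).
# RRM and ZnF are the structured (native-contact) domains; all others are
# disordered. CTRR denotes the C-terminal RGG-rich region RGG2..PY.
domains:
  PrLD:   {start: 1,   end: 165, kind: disordered}
  RGG1:   {start: 166, end: 284, kind: disordered}
  RRM:    {start: 285, end: 371, kind: structured}
  RGG2:   {start: 372, end: 421, kind: disordered}
  ZnF:    {start: 422, end: 453, kind: structured}
  RGG3PY: {start: 454, end: 526, kind: disordered}
composites:
  CTRR: [RGG2, ZnF, RGG3PY]
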