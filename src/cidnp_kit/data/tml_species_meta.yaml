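TMLHred:
  g_iso: 2.0034
  role: reduced
  protonation_label: anion
TMLH2red(H5):
  g_iso: 2.0033
  role: reduced
  protonation_label: N(5)-protonated
TMLH2red(H1):
  g_iso: 2.0034
  role: reduced
  protonation_label: N(1)-protonated
TMLox:
  g_iso: 2.0031
  role: oxidized
  protonation_label: neutral
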