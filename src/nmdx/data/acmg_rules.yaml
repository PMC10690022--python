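# ACMG/AMP evidence-combining rules, expressed as data so tests can enumerate them.
# Each rule counts evidence codes by strength bucket:
#   PVS  = PVS1
#   PS   = PS1..PS4
#   PM   = PM1..PM6
#   PP   = PP1..PP5
#   BA   = BA1
#   BS   = BS1..BS4
#   BP   = BP1..BP7
# A rule fires when every listed bucket count is >= the stated minimum.
# Pathogenic and Benign sides are evaluated independently; meeting both sides
# (Pathogenic/Likely-pathogenic AND Benign/Likely-benign) yields VUS (conflict).
version: "2015-combining-v1"
pathogenic:
  - {PVS: 1, PS: 1}
  - {PVS: 1, PM: 2}
  - {PVS: 1, PM: 1, PP: 1}
  - {PVS: 1, PP: 2}
  - {PS: 2}
  - {PS: 1, PM: 3}
  - {PS: 1, PM: 2, PP: 2}
  - {PS: 1, PM: 1, PP: 4}
likely_pathogenic:
  - {PVS: 1, PM: 1}
  - {PS: 1, PM: 1}
  - {PS: 1, PP: 2}
  - {PM: 3}
  - {PM: 2, PP: 2}
  - {PM: 1, PP: 4}
benign:
  - {BA: 1}
  - {BS: 2}
likely_benign:
  - {BS: 1, BP: 1}
  - {BP: 2}
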