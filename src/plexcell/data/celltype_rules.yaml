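# Default nine-type classification rules for inflammatory infiltrate.
# A rule matches a phenocluster when every required_positive marker is
# positive in at least a third of the cluster's cells and every
# required_negative marker in fewer than a third; among matches the
# highest priority wins. This table is a reconstruction from published
# phenotype descriptions (e.g. NK = CD45+ CD3- GranzymeB+ Granulysin+;
# TAM = CD16+ with restricted lineage markers CD68/CD163; inflammatory
# monocytes = LYZ+ VISTA+); it is data, not code - replace it to suit
# your panel.
rules:
  - type_name: CD4_T
    required_positive: [CD45, CD3, CD4]
    required_negative: [CD8]
    priority: 90
  - type_name: CD8_T
    required_positive: [CD45, CD3, CD8]
    required_negative: [CD4]
    priority: 89
  - type_name: NK
    required_positive: [CD45, GranzymeB, Granulysin]
    required_negative: [CD3]
    priority: 80
  - type_name: B
    required_positive: [CD45, CD20]
    required_negative: [CD3]
    priority: 79
  - type_name: TAM
    required_positive: [CD16, CD68, CD163]
    required_negative: [CD3]
    priority: 70
  - type_name: Histiocyte
    required_positive: [CD163]
    required_negative: [CD16, CD3]
    priority: 60
  - type_name: Phagocyte
    required_positive: [CD68]
    required_negative: [CD163, CD16, CD3]
    priority: 59
  - type_name: InflammatoryMonocyte
    required_positive: [LYZ, VISTA]
    required_negative: [CD68, CD163, CD3]
    priority: 50
  - type_name: MonoMac_undefined
    required_positive: [CD45]
    required_negative: [CD3, CD20]
    priority: 10
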