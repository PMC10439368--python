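"""Shared 7-tip fixture whose reference values were computed with the
independent R implementations (phytools, ape) and frozen in the tests."""

TREE8 = "((((A:0.3,B:0.3):0.4,C:0.7):0.3,(D:0.5,E:0.5):0.5):0.2,(F:0.9,G:0.9):0.3);"
TIPS7 = ["A", "B", "C", "D", "E", "F", "G"]
Y7 = {"A": 1.1524, "B": 1.4703, "C": 1.0639, "D": 0.5735,
      "E": 1.033, "F": 0.5704, "G": 1.4392}
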