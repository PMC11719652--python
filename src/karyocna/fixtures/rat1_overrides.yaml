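# Pinned explicit compositions for the two shorthand derivatives of the
# Rat-1 karyotype.  der(2) matches the default centromere-retention
# expansion; der(4) is pinned because the banding evidence (loss of
# distal 3q alongside monosomy 3, whole-chromosome loss of 4) implies the
# derivative keeps proximal 3 and distal 4, the opposite of what the
# default rule would produce for a der(4).
default: centromere_retention
overrides:
  "der(2)t(2;19)(q34;p11)":
    - 2pter->2q34
    - 19p11->19pter
  "der(4)t(3;4)(q?22;p11)":
    - 3pter->3q?22
    - 4p11->4qter
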