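# Placeholder OPEN triplet pools — NOT the published pool identities.
#
# Finger pools exist for all 16 GNN triplets and a subset of TNN (and one
# ANN) triplets at each position of a three-finger array; the exact TNN/ANN
# membership per position has not been published.  This file reproduces the
# known pool SIZES (26 / 21 / 23 triplets at positions 1 / 2 / 3) using all
# 16 GNN triplets plus provisional TNN choices, so that target-space
# combinatorics are exercised at the right scale.  Replace with real pool
# lists for production use.
#
# pos1 is the 5'-most triplet of the 9-bp target site.
pos1:  # 16 GNN + 10 provisional TNN = 26
  [GAA, GAC, GAG, GAT, GCA, GCC, GCG, GCT,
   GGA, GGC, GGG, GGT, GTA, GTC, GTG, GTT,
   TAA, TAC, TAG, TAT, TCA, TCC, TCG, TCT, TGA, TGC]
pos2:  # 16 GNN + 5 provisional TNN = 21
  [GAA, GAC, GAG, GAT, GCA, GCC, GCG, GCT,
   GGA, GGC, GGG, GGT, GTA, GTC, GTG, GTT,
   TAA, TAC, TAG, TAT, TCA]
pos3:  # 16 GNN + 7 provisional TNN = 23
  [GAA, GAC, GAG, GAT, GCA, GCC, GCG, GCT,
   GGA, GGC, GGG, GGT, GTA, GTC, GTG, GTT,
   TAA, TAC, TAG, TAT, TCA, TCC, TCG]
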