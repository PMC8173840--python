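# Default pathway gene lists for a feather-louse endosymbiont analysis.
# Standard bacterial (E. coli-style) gene names; edit or replace via
# `endosift.pathway_scoring.load_pathways(path)`.
histidine: [hisG, hisE, hisI, hisA, hisH, hisF, hisB, hisC, hisD]
lysine: [lysC, asd, dapA, dapB, dapD, argD, dapE, dapF, lysA]
methionine: [metA, metB, metC, metE, metH]
tryptophan: [trpA, trpB, trpC, trpD, trpE]
pantothenate: [panB, panC, panE]
coenzyme_a: [coaA, coaB, coaC, coaD]
folate: [folA, folB, folC, folE, folK, folP]
biotin: [bioA, bioB, bioC, bioD, bioF, bioH]
riboflavin: [ribA, ribB, ribC, ribD, ribE]
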