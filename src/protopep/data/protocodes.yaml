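# Protocode codon assignments over the two two-base alphabets.
#
# Four protocodes: dominant and recessive for each of the AU and GC base
# pairs.  Dominant and recessive protocodes compete for the same two-base
# codons (e.g. Phe vs Leu for UUU, Pro vs Ser for CCC).  Placeholders X1,
# X1* and X2 are amino acids that disappeared before the fusion of the
# protocodes into the standard genetic code; their deletion is the origin
# of the stop codons.  `complement_pairs` lists member pairs whose codons
# are reverse complements of each other; the recessive re-assignment must
# not break this pairing.
version: 1
protocodes:
  - name: AU-dominant
    bases: [A, U]
    dominance: dominant
    members:
      K: [AAA]
      N: [AAU]
      I: [AUU, AUA]
      F: [UUU]
      Y: [UAU]
      X1: {codons: [UAA], deleted: true}
      "X1*": {codons: [UUA], deleted: true}
    complement_pairs:
      - [F, K]        # UUU / AAA
      - [N, I]        # AAU / AUU
      - [Y, I]        # UAU / AUA
      - [X1, "X1*"]   # UAA / UUA
  - name: AU-recessive
    bases: [A, U]
    dominance: recessive
    members:
      E: [AAA]
      D: [AAU]
      V: [AUU, AUA]
      L: [UUU, UUA]
      Q: [UAA]
      H: [UAU]
    complement_pairs:
      - [L, E]        # UUU / AAA
      - [D, V]        # AAU / AUU
      - [H, V]        # UAU / AUA
      - [Q, L]        # UAA / UUA
  - name: GC-dominant
    bases: [G, C]
    dominance: dominant
    members:
      G: [GGG, GGC]
      P: [CCC, CCG]
      A: [GCC, GCG]
      R: [CGC, CGG]
    complement_pairs:
      - [G, P]        # GGG / CCC
      - [G, A]        # GGC / GCC
      - [A, R]        # GCG / CGC
      - [P, R]        # CCG / CGG
  - name: GC-recessive
    bases: [G, C]
    dominance: recessive
    members:
      # Ser and Arg are the "traveling" members: besides competing with Pro
      # for CCC/CCG, Ser also sits at GGC and Arg at GGG, which is what
      # routes AGU/AGC to Ser and AGA/AGG to Arg after fusion.
      S: [CCC, CCG, GGC]
      T: [GCC, GCG]
      C: [CGC]
      R: [GGG]
      X2: {codons: [CGG], deleted: true}
    complement_pairs:
      - [S, R]        # CCC / GGG
      - [S, T]        # GGC / GCC
      - [T, C]        # GCG / CGC
      - [S, X2]       # CCG / CGG
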