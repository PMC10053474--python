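# Residue property scales used for the sum-property analyses.
#
# Peptides on the array are N-terminally acetylated and attached to the
# surface through a C-terminal beta-alanine linker, so the termini carry no
# charge; the terminal adjustments below reflect that chemistry.
charge:
  name: charge
  units: e
  description: Net side-chain charge at pH 7.4 (K,R = +1; D,E = -1; H = 0).
  n_terminal: 0.0
  c_terminal: 0.0
  values:
    A: 0.0
    C: 0.0
    D: -1.0
    E: -1.0
    F: 0.0
    G: 0.0
    H: 0.0
    I: 0.0
    K: 1.0
    L: 0.0
    M: 0.0
    N: 0.0
    P: 0.0
    Q: 0.0
    R: 1.0
    S: 0.0
    T: 0.0
    V: 0.0
    W: 0.0
    Y: 0.0
hydrophobicity:
  name: hydrophobicity
  units: Kyte-Doolittle units
  description: Kyte-Doolittle hydropathy index.
  n_terminal: 0.0
  c_terminal: 0.0
  values:
    A: 1.8
    C: 2.5
    D: -3.5
    E: -3.5
    F: 2.8
    G: -0.4
    H: -3.2
    I: 4.5
    K: -3.9
    L: 3.8
    M: 1.9
    N: -3.5
    P: -1.6
    Q: -3.5
    R: -4.5
    S: -0.8
    T: -0.7
    V: 4.2
    W: -0.9
    Y: -1.3
helix_propensity:
  name: helix_propensity
  units: kcal/mol
  description: >
    Pace-Scholtz helix propensity (free energy cost relative to Ala; higher
    means less helix-favouring, Pro strongly helix-breaking).
  n_terminal: 0.0
  c_terminal: 0.0
  values:
    A: 0.0
    C: 0.68
    D: 0.69
    E: 0.40
    F: 0.54
    G: 1.0
    H: 0.61
    I: 0.41
    K: 0.26
    L: 0.21
    M: 0.24
    N: 0.65
    P: 3.16
    Q: 0.39
    R: 0.21
    S: 0.50
    T: 0.66
    V: 0.61
    W: 0.49
    Y: 0.53
molecular_weight:
  name: molecular_weight
  units: Da
  description: >
    Average residue (peptide-bond) masses; the N-terminal adjustment is the
    mass added by the acetyl cap.  The C-terminus is attached to the linker,
    so no free-acid water is added.
  n_terminal: 42.04
  c_terminal: 0.0
  values:
    A: 71.0788
    C: 103.1388
    D: 115.0886
    E: 129.1155
    F: 147.1766
    G: 57.0519
    H: 137.1411
    I: 113.1594
    K: 128.1741
    L: 113.1594
    M: 131.1926
    N: 114.1038
    P: 97.1167
    Q: 128.1307
    R: 156.1875
    S: 87.0782
    T: 101.1051
    V: 99.1326
    W: 186.2132
    Y: 163.1760
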