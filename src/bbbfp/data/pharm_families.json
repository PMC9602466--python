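{
  "version": 1,
  "families": ["HD", "HA", "AR", "HY", "BG", "AG"],
  "smarts": {
    "HD": ["[#7,#8;!H0]"],
    "HA": [
      "[OX2;H1;v2]",
      "[OX2;H0;!$(O=N);!$([OX2][NX3+])]",
      "[OX1;$([OX1]~[#6,#16,#15])]",
      "[O-;!$([O-]~[N+])]",
      "[NX3;H0;!+;v3;!$([N]~[OX1]);!$([N][!#6;!#1])]",
      "[NX2;!+;!$([N]=[O,S])]",
      "[nX2]"
    ],
    "AR": ["a1aaaaa1", "a1aaaa1"],
    "HY": [
      "[$([#6;+0;!$([#6]~[#7,#8,F]);!$([CH4])]),$([SX2;+0]),$([Cl;+0;D1]),$([Br;+0;D1]),$([I;+0;D1])]"
    ],
    "BG": [
      "[NX3;H2,H1;+0;!$(N[a]);!$(N[#6]=[O,N,S])]",
      "[NX3;H0;+0;!$(N[a]);!$(N[#6]=[O,N,S]);!$(N~[OX1])]",
      "[NX3][CX3](=[NX2])[NX3]",
      "[NX4+;!$([N+]~[-])]",
      "[NX3+;!$([N+]~[-])]"
    ],
    "AG": [
      "[CX3](=O)[OX2H1]",
      "[CX3](=O)[OX1-]",
      "[SX4](=O)(=O)[OX2H1]",
      "[SX4](=O)(=O)[OX1-]",
      "[PX4](=O)[OX2H1]",
      "[PX4](=O)[OX1-]",
      "c1nnn[nH]1",
      "c1nnn[n-]1"
    ]
  },
  "bins": [
    [1, 1], [2, 2], [3, 3], [4, 4], [5, 7], [8, 8], [9, 11],
    [12, 20], [21, 22], [23, 24], [25, 26], [27, 28], [29, null]
  ],
  "total_bits": 39971
}
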