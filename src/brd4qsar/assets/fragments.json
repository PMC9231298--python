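{
  "name": "synthetic-brd4-fragments",
  "version": "1.0",
  "comment": "Scaffold templates ({0}/{1} are substitution slots) and substituents spanning the typed-atom vocabulary: sulfone arms, alkoxy groups, aromatic N heterocycles, saturated carbocycles, basic amines, halogens.",
  "scaffolds": [
    "c1cc({0})cc({1})c1",
    "c1nc({0})cc({1})c1",
    "c1nc({0})nc({1})c1",
    "c1cc({0})c({1})cn1",
    "Cn1ccc({0})c1{1}",
    "c1cc({0})cc(c1)-c1ccc({1})nc1",
    "O=C(N{0})c1ccc({1})cc1",
    "C1CC({0})CCC1{1}",
    "c1cc({0})c2CCCCc2c1{1}",
    "c1ccc(Oc2ccc({0})cn2)cc1{1}"
  ],
  "substituents": [
    "",
    "C",
    "CC",
    "OC",
    "OCC",
    "CS(C)(=O)=O",
    "S(C)(=O)=O",
    "N",
    "NC",
    "CN(C)C",
    "CCN",
    "c1ccncc1",
    "c1ccccc1",
    "C1CC1",
    "C1CCCCC1",
    "N1CCOCC1",
    "C(=O)NC",
    "F",
    "Cl",
    "CC#N",
    "OC1CCCC1"
  ]
}
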