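{
 "_provenance": "Published QED parameterization: asymmetric-double-sigmoid desirability coefficients and property weights from Bickerton et al., 'Quantifying the chemical beauty of drugs', Nat. Chem. 4:90-98 (2012) (supplementary information / reference implementation); structural-alert SMARTS are the Brenk et al. ChemMedChem 3:435-444 (2008) unwanted-substructure set as distributed with that reference implementation; hydrogen-bond-acceptor SMARTS definitions likewise from the reference implementation.",
 "ads": {
  "MW": {
   "A": 2.817065973,
   "B": 392.5754953,
   "C": 290.7489764,
   "D": 2.419764353,
   "E": 49.22325677,
   "F": 65.37051707,
   "DMAX": 104.9805561
  },
  "ALOGP": {
   "A": 3.172690585,
   "B": 137.8624751,
   "C": 2.534937431,
   "D": 4.581497897,
   "E": 0.822739154,
   "F": 0.576295591,
   "DMAX": 131.3186604
  },
  "HBA": {
   "A": 2.948620388,
   "B": 160.4605972,
   "C": 3.615294657,
   "D": 4.435986202,
   "E": 0.290141953,
   "F": 1.300669958,
   "DMAX": 148.7763046
  },
  "HBD": {
   "A": 1.618662227,
   "B": 1010.051101,
   "C": 0.985094388,
   "D": 1e-09,
   "E": 0.713820843,
   "F": 0.920922555,
   "DMAX": 258.1632616
  },
  "PSA": {
   "A": 1.876861559,
   "B": 125.2232657,
   "C": 62.90773554,
   "D": 87.83366614,
   "E": 12.01999824,
   "F": 28.51324732,
   "DMAX": 104.5686167
  },
  "ROTB": {
   "A": 0.01,
   "B": 272.4121427,
   "C": 2.55837997,
   "D": 1.565547684,
   "E": 1.271567166,
   "F": 2.758063707,
   "DMAX": 105.4420403
  },
  "AROM": {
   "A": 3.21778897,
   "B": 957.7374108,
   "C": 2.274627939,
   "D": 1e-09,
   "E": 1.317690384,
   "F": 0.375760881,
   "DMAX": 312.337261
  },
  "ALERTS": {
   "A": 0.01,
   "B": 1199.094025,
   "C": -0.09002883,
   "D": 1e-09,
   "E": 0.185904477,
   "F": 0.875193782,
   "DMAX": 417.725314
  }
 },
 "weights_mean": {
  "MW": 0.66,
  "ALOGP": 0.46,
  "HBA": 0.05,
  "HBD": 0.61,
  "PSA": 0.06,
  "ROTB": 0.65,
  "AROM": 0.48,
  "ALERTS": 0.95
 },
 "acceptor_smarts": [
  "[o&H0&X2]",
  "[O&H1&X2&v2]",
  "[O&H0&X2&v2]",
  "[O&H0&X1&v2]",
  "[O&-&X1]",
  "[S&H0&X2&v2]",
  "[S&H0&X1&v2]",
  "[S&-&X1]",
  "[n&H0&X2]",
  "[N&H0&X1&v3]",
  "[$([N&+0&X3&v3])&!$(N[C,S]=O)]"
 ],
 "alert_smarts": [
  "*1[O,S,N]*1",
  "[S,C](=[O,S])[F,Br,Cl,I]",
  "[C&X4][Cl,Br,I]",
  "[#6]S(=O)(=O)O[#6]",
  "[$([C&H1]),$(CC)]#CC(=O)[#6]",
  "[$([C&H1]),$(CC)]#CC(=O)O[#6]",
  "n[O&H1]",
  "[$([C&H1]),$(CC)]#CS(=O)(=O)[#6]",
  "C=C(C=O)C=O",
  "n1c([F,Cl,Br,I])cccc1",
  "[C&H1]=O",
  "[#8][#8]",
  "[C&!R]=[N&!R]",
  "[N&!R]=[N&!R]",
  "[#6](=O)[#6]=O",
  "[#16][#16]",
  "[#7][N&H2]",
  "C(=O)N[N&H2]",
  "[#6]=S",
  "[$([C&H2]),$([C&H1][C&X4]),$(C([C&X4])[C&X4])]=[$([C&H2]),$([C&H1][C&X4]),$(C([C&X4])[C&X4])]",
  "C1(=[O,N])C=CC(=[O,N])C=C1",
  "C1(=[O,N])C(=[O,N])C=CC=C1",
  "a12aa3a(aa1aaaa2)aaaa3",
  "a12a(a3a(aa1)aaaa3)aaaa2",
  "a1aa2a3a(a1)A=AA=A3=AA=A2",
  "c1cc([N&H2])ccc1",
  "[#80,#26,#33,#51,#30,#34,se,#52,B,#14,#11,#20,#32,#47,#12,#19,#56,#38,#4,#22,#42,#25,#44,#46,#28,#29,#79,#48,#13,#31,#50,#45,#81,#83,#41,#3,#82,#72,#67]",
  "I",
  "OS(=O)(=O)[O&-]",
  "[N&+](=O)[O&-]",
  "C(=O)N[O&H1]",
  "C1NC(=O)NC1=O",
  "[S&H1]",
  "[S&-]",
  "c1ccc([Cl,Br,I,F])c([Cl,Br,I,F])c1[Cl,Br,I,F]",
  "c1cc([Cl,Br,I,F])cc([Cl,Br,I,F])c1[Cl,Br,I,F]",
  "[C&R1]1[C&R1][C&R1][C&R1][C&R1][C&R1][C&R1]1",
  "[C&R1]1[C&R1][C&R1]cc[C&R1][C&R1]1",
  "[C&R2]1[C&R2][C&R2][C&R2][C&R2][C&R2][C&R2][C&R2]1",
  "[C&R2]1[C&R2][C&R2]cc[C&R2][C&R2][C&R2]1",
  "[C&H2&R2]1N[C&H2&R2][C&H2&R2][C&H2&R2][C&H2&R2][C&H2&R2]1",
  "[C&H2&R2]1N[C&H2&R2][C&H2&R2][C&H2&R2][C&H2&R2][C&H2&R2][C&H2&R2]1",
  "C#C",
  "[O&R2,N&R2]@[C&R2]@[C&R2]@[O&R2,N&R2]@[C&R2]@[C&R2]@[O&R2,N&R2]",
  "[$([N&+&R]),$([n&+&R]),$([N&+]=C)][O&-]",
  "[#6]=N[O&H1]",
  "[#6]=NOC=O",
  "[#6](=O)[C&X4,C&R0&X3,O][#6]=O",
  "c1ccc2c(c1)ccc(=O)o2",
  "[O&+,o&+,S&+,s&+]",
  "N=C=O",
  "[N&X3,N&X4][F,Cl,Br,I]",
  "c1ccccc1OC(=O)[#6]",
  "[C&R0]=[C&R0][C&R0]=[C&R0]",
  "[C&+,c&+,C&-,c&-]",
  "N=[N&+]=[N&-]",
  "C12C(NC(N1)=O)CSC2",
  "c1c([O&H1])c([O&H1,N&H2,N&H1])ccc1",
  "P",
  "[N,O,S]C#N",
  "C=C=O",
  "[#14][F,Cl,Br,I]",
  "[S&X2]O",
  "[#14&R0,C&R0](c1ccccc1)(c1ccccc1)c1ccccc1",
  "O1CCCCC1OC1CCC2CCCCC2C1",
  "N=[C&R0][N,n,O,S]",
  "[c&R2]1[c&R2][c&R2]([N&v3&X3,N&v4&X4])[c&R2][c&R2][c&R2]1[c&R2]1[c&R2][c&R2][c&R2]([N&v3&X3,N&v4&X4])[c&R2][c&R2]1",
  "C=[C&!R]C#N",
  "[c&R2]1[c&R2]c([N&+0&X3&R0,n&X3&R0])c([N&+0&X3&R0,n&X3&R0])[c&R2][c&R2]1",
  "[c&R2]1[c&R2]c([N&+0&X3&R0,n&X3&R0])[c&R2]c([N&+0&X3&R0,n&X3&R0])[c&R2]1",
  "[c&R2]1[c&R2]c([N&+0&X3&R0,n&X3&R0])[c&R2][c&R2]c1[N&+0&X3&R0,n&X3&R0]",
  "[O&H1]c1ccc([O&H1,N&H2,N&H1])cc1",
  "c1ccccc1OC(=O)O",
  "[S&X2&H0]N",
  "c12ccccc1SC(S)=N2",
  "c12ccccc1SC(=S)N2",
  "c1nnnn1C=O",
  "s1c(S)nnc1NC=O",
  "S1C=CSC1=S",
  "C(=O)Onnn",
  "OS(=O)(=O)C(F)(F)F",
  "N#CC[O&H1]",
  "N#CC=O",
  "S(=O)(=O)C#N",
  "N[C&H2]C#N",
  "C1(=O)NCC1",
  "S(=O)(=O)[O&-,O&H1]",
  "NC[F,Cl,Br,I]",
  "C=[C&!R]O",
  "[N&X2&+0]=[O&+0]",
  "[O&R0,N&R0][O&R0,N&R0]",
  "C(=O)O[C,H1].C(=O)O[C,H1].C(=O)O[C,H1]",
  "[C&X2&R0][N&X3&R0]",
  "c1ccccc1[C&!R]=[C&!R]c1ccccc1",
  "[N&X3&R0,N&X4&R0,O&R0,S&X2&R0][C&X4][N&X3&R0,N&X4&R0,O&R0,S&X2&R0]",
  "[s,S,c,C,n,N,o,O]~[n&+,N&+](~[s,S,c,C,n,N,o,O])(~[s,S,c,C,n,N,o,O])~[s,S,c,C,n,N,o,O]",
  "[s,S,c,C,n,N,o,O]~[n&X3&+,N&X3&+](~[s,S,c,C,n,N])~[s,S,c,C,n,N]",
  "*=[N&+]=*",
  "[S&X3](=O)[O&-,O&H1]",
  "N#N",
  "F.F.F.F",
  "[R0&D2][R0&D2][R0&D2][R0&D2]",
  "[c&R,C&R]~C(=O)NC(=O)~[c&R,C&R]",
  "C=&!@CC=[O,S]",
  "[#6,#8,#16][#6](=O)O[#6]",
  "c[C&R0](=[O,S])[#6]",
  "c[S&X2][C&!R]",
  "C=C=C",
  "c1nc([F,Cl,Br,I,S])ncc1",
  "c1ncnc([F,Cl,Br,I,S])c1",
  "c1ncc2c(n1)nc(n2)[F,Cl,Br,I]",
  "[#6]S(=O)(=O)c1ccc(cc1)F",
  "[N&15*]",
  "[C&13*]",
  "[O&18*]",
  "[S&34*]"
 ]
}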