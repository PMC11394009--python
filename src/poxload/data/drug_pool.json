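{
  "curcumin": "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O",
  "paclitaxel": "CC(=O)O[C@@H]1C2=C(C)[C@H](C[C@@](O)([C@@H](OC(=O)c3ccccc3)[C@@H]3[C@@]4(CO[C@@H]4C[C@H](O)[C@@]3(C)C1=O)OC(C)=O)C2(C)C)OC(=O)[C@H](O)[C@@H](NC(=O)c1ccccc1)c1ccccc1",
  "triamcinolone acetonide": "CC1(C)O[C@@H]2C[C@H]3[C@@H]4CCC5=CC(=O)C=C[C@]5(C)[C@@]4(F)[C@@H](O)C[C@]3(C)[C@]2(O1)C(=O)CO",
  "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
  "efavirenz": "O=C1Nc2ccc(Cl)cc2C(C#CC2CC2)(C(F)(F)F)O1",
  "indomethacin": "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",
  "cannabidiol": "CCCCCc1cc(O)c(C2CC(C)=CCC2C(=C)C)c(O)c1",
  "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
  "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
  "ketoprofen": "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",
  "fenofibrate": "CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1",
  "griseofulvin": "COC1=CC(=O)CC(C)C12Oc1c(Cl)c(OC)cc(OC)c1C2=O",
  "clotrimazole": "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1",
  "carbamazepine": "NC(=O)N1c2ccccc2C=Cc2ccccc21",
  "nifedipine": "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",
  "felodipine": "CCOC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1cccc(Cl)c1Cl",
  "dexamethasone": "C[C@@H]1C[C@H]2[C@@H]3CCC4=CC(=O)C=C[C@]4(C)[C@@]3(F)[C@@H](O)C[C@]2(C)[C@@]1(O)C(=O)CO",
  "estradiol": "C[C@]12CC[C@H]3c4ccc(O)cc4CC[C@@H]3[C@@H]1CC[C@@H]2O",
  "testosterone": "C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]34C)[C@@H]1CC[C@@H]2O",
  "progesterone": "CC(=O)[C@H]1CC[C@H]2[C@@H]3CCC4=CC(=O)CC[C@]4(C)[C@H]3CC[C@]12C",
  "tamoxifen": "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
  "quercetin": "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
  "resveratrol": "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1",
  "haloperidol": "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",
  "diazepam": "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
  "phenytoin": "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",
  "amiodarone": "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1",
  "vismodegib": "CS(=O)(=O)c1ccc(Cl)c(C(=O)Nc2ccc(Cl)c(-c3ccccn3)c2)c1",
  "olanzapine": "CN1CCN(C2=Nc3ccccc3Nc3sc(C)cc32)CC1",
  "mitotane": "ClC(Cl)C(c1ccc(Cl)cc1)c1ccccc1Cl",
  "nimesulide": "CS(=O)(=O)Nc1ccc([N+](=O)[O-])cc1Oc1ccccc1"
}
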