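{
  "MeOx":    {"role": "A", "smiles": "[*:1]N(C(C)=O)CC[*:2]"},
  "EtOx":    {"role": "A", "smiles": "[*:1]N(C(=O)CC)CC[*:2]"},
  "nPrOx":   {"role": "B", "smiles": "[*:1]N(C(=O)CCC)CC[*:2]"},
  "nBuOx":   {"role": "B", "smiles": "[*:1]N(C(=O)CCCC)CC[*:2]"},
  "PentOx":  {"role": "B", "smiles": "[*:1]N(C(=O)CCCCC)CC[*:2]"},
  "BzOx":    {"role": "B", "smiles": "[*:1]N(C(=O)Cc1ccccc1)CC[*:2]"},
  "PhOx":    {"role": "B", "smiles": "[*:1]N(C(=O)c1ccccc1)CC[*:2]"},
  "PhenOx":  {"role": "B", "smiles": "[*:1]N(C(=O)CCc1ccccc1)CC[*:2]"},
  "nPrOzi":  {"role": "B", "smiles": "[*:1]N(C(=O)CCC)CCC[*:2]"},
  "nBuOzi":  {"role": "B", "smiles": "[*:1]N(C(=O)CCCC)CCC[*:2]"},
  "BzOzi":   {"role": "B", "smiles": "[*:1]N(C(=O)Cc1ccccc1)CCC[*:2]"},
  "PhOzi":   {"role": "B", "smiles": "[*:1]N(C(=O)c1ccccc1)CCC[*:2]"},
  "PhenOzi": {"role": "B", "smiles": "[*:1]N(C(=O)CCc1ccccc1)CCC[*:2]"},
  "Me":      {"role": "terminus_start", "smiles": "C[*:1]"},
  "Pip":     {"role": "terminus_end", "smiles": "[*:1]N1CCCCC1"},
  "OH":      {"role": "terminus_end", "smiles": "O[*:1]"}
}
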