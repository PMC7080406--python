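smiles,template_id,expect_pass,fail_reason,note
CC(=O)NCCc1c[nH]c2ccc(OC)cc12,melatonin,True,,N-acetyl-5-methoxytryptamine; 17 heavy atoms
NC(=O)NCCc1c[nH]c2ccc(OC)cc12,mel_urea,True,,urea analog of melatonin (acetamide -> urea)
CC(=O)NCCc1ccc2ccc(OC)cc2c1,naphthalene_amide,True,,agomelatine-like naphthalene core
CC(=O)NCCc1c[nH]c2ccccc12,indole_amide,True,,N-acetyltryptamine
CC(=O)NCCc1ccc(OC)cc1,methoxyphenyl_amide,True,,open-chain methoxyphenyl chemotype
CC(=O)NCc1ccc2sccc2n1,thienopyridine_amide,True,,fused thienopyridine chemotype
Clc1ccc(-c2ccc(CNC(C)=O)[nH]2)cc1,chlorophenyl_pyrrole,True,,chlorophenyl-pyrrole chemotype
COc1ccc2ccccc2c1CCN,naphthyl_ether_amine,True,,methoxynaphthalene ethylamine
CC(=O)NCCc1cc2ccccc2o1,benzofuran_amide,True,,benzofuran bioisostere
Cc1ccccc1CNC(C)=O,toluene_amide,True,,small benzylamide fragment
CC(=O)NCCc1c[nH]c2ccc(OCc3ccc(OC)cc3)cc12,big_mw,False,mw,MW 338 exceeds the 250 Da ceiling
CCCCCCCCCCCCc1ccccc1,logp_high,False,logp,dodecylbenzene; logP 6.2 above the 1-5 window
C[N+](C)(C)CCCC[N+](C)(C)C,dication,False,charge,formal charge +2 outside -1..+1
O=Cc1ccc(OC)cc1CC,aldehyde_reactive,False,reactive,aromatic aldehyde; reactive-group list
O=C1CSC(=S)N1c1ccccc1,pains_rhodanine,False,pains,N-phenyl rhodanine; PAINS rhod_sat_A
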