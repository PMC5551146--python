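id,name,chem_class,smiles,role,parent_id
bensulide,Bensulide,organophosphorus,CC(C)OP(=S)(OC(C)C)SCCNS(=O)(=O)c1ccccc1,parent,
chlorpyrifos,Chlorpyrifos,organophosphorus,CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,parent,
chlorpyrifos-methyl,Chlorpyrifos-methyl,organophosphorus,COP(=S)(OC)Oc1nc(Cl)c(Cl)cc1Cl,parent,
coumaphos,Coumaphos,organophosphorus,CCOP(=S)(OCC)Oc1ccc2oc(=O)c(Cl)c(C)c2c1,parent,
diazinon,Diazinon,organophosphorus,CCOP(=S)(OCC)Oc1cc(C)nc(C(C)C)n1,parent,
ethion,Ethion,organophosphorus,CCOP(=S)(OCC)SCSP(=S)(OCC)OCC,parent,
fenthion,Fenthion,organophosphorus,COP(=S)(OC)Oc1ccc(SC)c(C)c1,parent,
fonofos,Fonofos,organophosphorus,CCP(=S)(OCC)Sc1ccccc1,parent,
malathion,Malathion,organophosphorus,CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC,parent,
methyl-parathion,Methyl-parathion,organophosphorus,COP(=S)(OC)Oc1ccc([N+](=O)[O-])cc1,parent,
parathion,Parathion,organophosphorus,CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1,parent,
phorate,Phorate,organophosphorus,CCOP(=S)(OCC)SCSCC,parent,
phosmet,Phosmet,organophosphorus,COP(=S)(OC)SCN1C(=O)c2ccccc2C1=O,parent,
sulprofos,Sulprofos,organophosphorus,CCCSP(=S)(OCC)Oc1ccc(SC)cc1,parent,
terbufos,Terbufos,organophosphorus,CCOP(=S)(OCC)SCSC(C)(C)C,parent,
bensulide-oxon,Bensulide-oxon,organophosphorus,CC(C)OP(=O)(OC(C)C)SCCNS(=O)(=O)c1ccccc1,oxon_metabolite,bensulide
chlorpyrifos-oxon,Chlorpyrifos-oxon,organophosphorus,CCOP(=O)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,oxon_metabolite,chlorpyrifos
chlorpyrifos-methyl-oxon,Chlorpyrifos-methyl-oxon,organophosphorus,COP(=O)(OC)Oc1nc(Cl)c(Cl)cc1Cl,oxon_metabolite,chlorpyrifos-methyl
coumaphos-oxon,Coumaphos-oxon,organophosphorus,CCOP(=O)(OCC)Oc1ccc2oc(=O)c(Cl)c(C)c2c1,oxon_metabolite,coumaphos
diazinon-oxon,Diazoxon,organophosphorus,CCOP(=O)(OCC)Oc1cc(C)nc(C(C)C)n1,oxon_metabolite,diazinon
ethion-oxon,Ethion-monoxon,organophosphorus,CCOP(=O)(OCC)SCSP(=S)(OCC)OCC,oxon_metabolite,ethion
fenthion-oxon,Fenthion-oxon,organophosphorus,COP(=O)(OC)Oc1ccc(SC)c(C)c1,oxon_metabolite,fenthion
fonofos-oxon,Fonofos-oxon,organophosphorus,CCP(=O)(OCC)Sc1ccccc1,oxon_metabolite,fonofos
malathion-oxon,Malaoxon,organophosphorus,CCOC(=O)CC(SP(=O)(OC)OC)C(=O)OCC,oxon_metabolite,malathion
methyl-parathion-oxon,Methyl-paraoxon,organophosphorus,COP(=O)(OC)Oc1ccc([N+](=O)[O-])cc1,oxon_metabolite,methyl-parathion
parathion-oxon,Paraoxon,organophosphorus,CCOP(=O)(OCC)Oc1ccc([N+](=O)[O-])cc1,oxon_metabolite,parathion
phorate-oxon,Phorate-oxon,organophosphorus,CCOP(=O)(OCC)SCSCC,oxon_metabolite,phorate
phosmet-oxon,Phosmet-oxon,organophosphorus,COP(=O)(OC)SCN1C(=O)c2ccccc2C1=O,oxon_metabolite,phosmet
sulprofos-oxon,Sulprofos-oxon,organophosphorus,CCCSP(=O)(OCC)Oc1ccc(SC)cc1,oxon_metabolite,sulprofos
terbufos-oxon,Terbufos-oxon,organophosphorus,CCOP(=O)(OCC)SCSC(C)(C)C,oxon_metabolite,terbufos
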