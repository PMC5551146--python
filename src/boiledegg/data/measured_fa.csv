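id,name,chem_class,smiles,fa,fa_qualifier,source_note
cypermethrin,Cypermethrin,pyrethroid,CC1(C)C(C=C(Cl)Cl)C1C(=O)OC(C#N)c1cccc(Oc2ccccc2)c1,0.40,=,human pharmacokinetics
deltamethrin,Deltamethrin,pyrethroid,CC1(C)C(C=C(Br)Br)C1C(=O)OC(C#N)c1cccc(Oc2ccccc2)c1,0.48,>,urinary excretion bound
permethrin,Permethrin,pyrethroid,CC1(C)C(C=C(Cl)Cl)C1C(=O)OCc1cccc(Oc2ccccc2)c1,0.32,>=,urinary excretion bound
bendiocarb,Bendiocarb,carbamate,CNC(=O)Oc1cccc2c1OC(C)(C)O2,0.99,>=,human pharmacokinetics
pirimicarb,Pirimicarb,carbamate,CN(C)C(=O)Oc1nc(N(C)C)nc(C)c1C,0.74,=,human pharmacokinetics
molinate,Molinate,carbamate,CCSC(=O)N1CCCCCC1,0.40,>,urinary excretion bound
propoxur,Propoxur,carbamate,CNC(=O)Oc1ccccc1OC(C)C,0.37,>,urinary excretion bound
ddt,DDT,organochlorine,Clc1ccc(C(c2ccc(Cl)cc2)C(Cl)(Cl)Cl)cc1,0.15,=,human pharmacokinetics
pentachlorophenol,Pentachlorophenol,organochlorine,Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl,0.86,>,urinary excretion bound
tcdd,TCDD,organochlorine,Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl,0.87,>,human pharmacokinetics
chlorpyrifos,Chlorpyrifos,organophosphorus,CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl,0.82,=,human pharmacokinetics
diazinon,Diazinon,organophosphorus,CCOP(=S)(OCC)Oc1cc(C)nc(C(C)C)n1,0.66,>,urinary excretion bound
dichlorvos,Dichlorvos,organophosphorus,COP(=O)(OC)OC=C(Cl)Cl,0.36,>,urinary excretion bound
dimethoate,Dimethoate,organophosphorus,CNC(=O)CSP(=S)(OC)OC,0.86,=,human pharmacokinetics
fenitrothion,Fenitrothion,organophosphorus,COP(=S)(OC)Oc1ccc([N+](=O)[O-])c(C)c1,0.81,=,human pharmacokinetics
parathion,Parathion,organophosphorus,CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1,0.46,>,urinary excretion bound
propetamphos,Propetamphos,organophosphorus,CCNP(=S)(OC)OC(C)=CC(=O)OC(C)C,0.41,>,urinary excretion bound
245-t,"2,4,5-T",miscellaneous,OC(=O)COc1cc(Cl)c(Cl)cc1Cl,0.89,>,urinary excretion bound
24-d,"2,4-D",miscellaneous,OC(=O)COc1ccc(Cl)cc1Cl,0.85,=,human pharmacokinetics
fluazifop-butyl,Fluazifop-butyl,miscellaneous,CCCCOC(=O)C(C)Oc1ccc(Oc2ccc(C(F)(F)F)cn2)cc1,0.88,=,human pharmacokinetics
mcpa,MCPA,miscellaneous,OC(=O)COc1ccc(Cl)cc1C,0.55,>,urinary excretion bound
paraquat,Paraquat,miscellaneous,C[n+]1ccc(-c2cc[n+](C)cc2)cc1,0.05,<=,human pharmacokinetics
picloram,Picloram,miscellaneous,OC(=O)c1nc(Cl)c(Cl)c(N)c1Cl,0.91,=,human pharmacokinetics
triclopyr,Triclopyr,miscellaneous,OC(=O)COc1nc(Cl)c(Cl)cc1Cl,0.82,>,urinary excretion bound
warfarine,Warfarine,miscellaneous,CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O,0.93,>,human pharmacokinetics
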