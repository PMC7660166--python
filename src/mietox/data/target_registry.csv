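aid,mie_name,activity_type,abbreviation
720516,ATAD5,genotoxic inducer,ATAD5_ind
720552,p53,agonist,p53_ago
720637,mitochondrial membrane potential,disruptor,MMP_disr
720719,glucocorticoid receptor,agonist,GR_ago
720725,glucocorticoid receptor,antagonist,GR_ant
743053,androgen receptor lbd,agonist,Arlbd_ago
743054,androgen receptor full,antagonist,ARfull_ant
743063,androgen receptor lbd,antagonist,Arlbd_ant
743067,thyroid receptor,antagonist,TR_ant
743077,estrogen receptor alpha lbd,agonist,ERlbd_ago
743078,estrogen receptor alpha lbd,antagonist,ERlbd_ant
743091,estrogen receptor alpha full,antagonist,ERfull_ant
743122,aryl hydrocarbon receptor,agonist,AhR_ago
743139,aromatase,antagonist,Arom_ant
743140,peroxisome proliferator-activated receptor gamma,agonist,PPARg_ago
743199,peroxisome proliferator-activated receptor gamma,antagonist,PPARg_ant
743219,antioxidant response element,agonist,ARE_ago
743226,peroxisome proliferator-activated receptor delta,antagonist,PPARd_ant
743227,peroxisome proliferator-activated receptor delta,agonist,PPARd_ago
743228,heat shock response,activator,HSR_act
743239,farnesoid-X-receptor,agonist,FXR_ago
743240,farnesoid-X-receptor,antagonist,FXR_ant
743241,vitamin D receptor,agonist,VDR_ago
743242,vitamin D receptor,antagonist,VDR_ant
1159518,NFkB,agonist,NFkB_ago
1159519,endoplasmic reticulum stress response,agonist,ERsr_ago
1159523,retinoid-related orphan receptor gamma,antagonist,ROR_ant
1159528,activator protein-1,agonist,AP1_ago
1159531,retinoid X receptor-alpha,agonist,RXR_ago
1159555,retinoic acid receptor,antagonist,RAR_ant
1224892,constitutive androstane receptor,agonist,CAR_ago
1224893,constitutive androstane receptor,antagonist,CAR_ant
1224894,hypoxia,agonist,HIF1_ago
1224895,thyroid stimulating hormone receptor,agonist,TSHR_ago
1224896,histone variant H2AX,agonist,H2AX_ago
1259247,androgen receptor with stimulator,antagonist,Arfulls_ant
1259248,estrogen receptor alpha with stimulator,antagonist,Erfulls_ant
1259387,androgen receptor with antagonist,agonist,ARant_ago
1259388,histone deacetylase,antagonist,HDAC_ant
1259390,sonic hedgehog signaling,agonist,Shh_ago
1259391,estrogen receptor alpha with antagonist,agonist,ERaant_ago
1259392,sonic hedgehog signaling,antagonist,Shh_ant
1259393,thyroid stimulating hormone receptor,agonist antagonist,TSHR_agoant
1259394,estrogen receptor beta,agonist,ERb_ago
1259395,thyroid stimulating hormone receptor,antagonist,TSHR_ant
1259396,estrogen receptor beta,antagonist,Erb_ant
1259401,estrogen related receptor with PGC,antagonist,ERRPGC_ant
1259402,estrogen related receptor with PGC,agonist,ERRPGC_ago
1259403,estrogen related receptor,antagonist,ERR_ant
1259404,estrogen related receptor,agonist,ERR_ago
1347030,thyrotropin releasing hormone receptor,agonist,TRHR_ago
1347031,progesterone receptor,antagonist,PR_ant
1347032,transforming growth factor beta,antagonist,TGFb_ant
1347033,human pregnane X receptor,agonist,PXR_ago
1347034,caspase-3/7 in HepG2,inducer,CaspH_ind
1347035,transforming growth factor beta,agonist,TGFb_ago
1347036,progesterone receptor,agonist,PR_ago
1347037,caspase-3/7 in CHO-K1,inducer,CaspC_ind
1347038,thyrotropin releasing hormone receptor,antagonist,TRHR_ant
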