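name,target_complex,cas,mol_weight,clogp,subset_flag,sim_mechanism,sim_potency_log10M,sim_hill_slope
Capsaicin,CI,404-86-4,305.20,3.64,True,inhibitor,-3.59,2.0
Deguelin,CI,522-17-8,394.14,4.26,True,inhibitor,-6.17,2.0
Fenazaquin,CI,120928-09-8,306.17,5.51,False,inhibitor,-5.59,2.0
Fenpyroximate,CI,134098-61-6,421.20,5.01,True,inhibitor,-6.17,2.0
Pyridaben,CI,96489-71-3,364.14,5.24,False,inhibitor,-5.49,2.0
Pyrimidifen,CI,105779-78-0,377.19,5.03,True,inhibitor,-7.10,2.0
Rotenone,CI,83-79-4,394.14,4.10,True,inhibitor,-6.62,2.0
Tebufenpyrad,CI,119168-77-3,333.16,4.93,True,inhibitor,-6.07,2.0
Carboxin,CII,5234-68-4,235.07,2.22,True,inhibitor,-4.63,2.0
Fenfuram,CII,24691-80-3,201.08,2.24,False,inhibitor,-3.30,2.0
Flutolanil,CII,66332-96-5,323.11,3.70,False,inhibitor,-4.16,2.0
Mepronil,CII,55814-41-0,269.14,3.90,True,inhibitor,-3.75,2.0
Thifluzamide,CII,130000-40-7,525.84,5.05,True,inhibitor,-4.71,2.0
Antimycin A,CIII,1397-94-0,548.27,4.41,True,inhibitor,-7.55,2.0
Azoxystrobin,CIII,131860-33-8,403.12,2.50,True,inhibitor,-4.77,2.0
Cyazofamid,CIII,120116-88-3,324.04,3.20,True,uncoupler,-5.88,2.0
Fenamidone,CIII,161326-34-7,311.11,3.72,False,inhibitor,-5.14,2.0
Kresoxim-methyl,CIII,143390-89-0,313.13,3.40,False,inhibitor,-5.04,2.0
Picoxystrobin,CIII,117428-22-5,367.10,3.81,True,inhibitor,-5.63,2.0
Pyraclostrobin,CIII,175013-18-0,387.10,3.99,True,inhibitor,-5.86,2.0
Trifloxystrobin,CIII,141517-21-7,408.13,4.50,False,inhibitor,-5.39,2.0
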