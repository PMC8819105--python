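chemical,abbreviation,sum_abc,animal_label,limb_flag
all-trans-Retinoic acid,ATRA,65.85,P,1
Hydroxyurea,HU,63.29,P,1
Methoxyacetic acid,MAA,225.30,P,1
Methylmercury chloride,MeHg,77.73,P,1
Methotrexate hydrate,MTX,80.48,P,1
Sodium salicylate,SA,38.69,P,1
Valproic acid,VPA,91.74,P,1
6-Aminonicotinamide,6-AN,24.88,P,0
Boric acid,BA,24.18,P,0
5-Bromo-2'-deoxyuridine,BrdU,83.91,P,0
"5,5-Dimethyl-2,4-oxazolidinedione",DMO,50.29,P,0
Lithium chloride,LiCl,29.75,P,0
Acrylamide,AcA,37.09,N,0
D-Camphor,CAM,27.48,N,0
Diphenhydramine hydrochloride,DHM,68.18,N,0
Dimethyl phthalate,DMP,24.41,N,0
Penicillin G sodium salt,PenG,22.12,N,0
Sodium saccharin,SAC,33.99,N,0
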