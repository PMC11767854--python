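wavenumber	observed_in	assignment	note
1240	cells;EVs	PO2- asymmetric stretching of phosphorylated proteins, phospholipids, and nucleic acids; C-O-P stretching (phosphorylated proteins and lipids)
1221	EVs	PO2- asymmetric stretching of phosphorylated proteins, phospholipids, and nucleic acids; C-O-P stretching (phosphorylated proteins and lipids)
1172	EVs	C-O stretching of C-OH groups of serine, threonine, and tyrosine in proteins and of carbohydrates (proteins, carbohydrates/glycogen); C-O stretching (nucleic acids); CO-O-C asymmetric stretching of ester bonds in cholesteryl esters (carbohydrates)
1170	cells	C-O stretching of C-OH groups of serine, threonine, and tyrosine in proteins and of carbohydrates (proteins, carbohydrates/glycogen); C-O stretching (nucleic acids); CO-O-C asymmetric stretching of ester bonds in cholesteryl esters (carbohydrates)
1158	cells;EVs	C-O stretching, C-C stretching, and C-O-H bending (glycogen/carbohydrate and proteins)
1121	cells;EVs	C-O stretching of C-OH group of ribose and carbohydrates (RNA, carbohydrates)
1110	cells;EVs	CC-OC stretching of ribose (RNA); symmetric stretching C-O-P; carbohydrates
1102	EVs	CC-OC stretching of ribose (RNA); symmetric stretching C-O-P; carbohydrates	interpolated from neighbouring band 1110
1085	cells;EVs	PO2- symmetric stretching of phosphorylated proteins, phospholipids, glycogen, and nucleic acids; C-O-P stretching (phosphorylated proteins and lipids)
1056	EVs	C-O stretching and C-OH bending (nucleic acids, phospholipid phosphate, glycogen, and other carbohydrates)
1053	cells	C-O stretching and C-OH bending (nucleic acids, phospholipid phosphate, glycogen, and other carbohydrates)
1039	cells	C-O stretching (lipid, carbohydrate); C-O stretching and C-OH bending (nucleic acids and carbohydrates); glycogen vibration
1031	EVs	C-O stretching (lipid, carbohydrate); C-O stretching and C-OH bending (nucleic acids and carbohydrates); glycogen vibration
1022	cells	C-O stretching and C-OH bending (nucleic acids and carbohydrates); C-O and C-C stretching and C-O-H deformation (glycogen)
991	EVs	C-O stretching from RNA ribose chain and other carbohydrates (nucleic acids ribose); RNA ribose phosphate main chain mode; C-C stretching of DNA backbone
988	cells	C-O stretching from RNA ribose chain and other carbohydrates (nucleic acids ribose); RNA ribose phosphate main chain mode; C-C stretching of DNA backbone
969	cells;EVs	PO32- symmetric stretching of nucleic acids and phosphorylated proteins; C-C, C-O, and C-N-C stretching of phosphodiester, deoxyribose and ribose (nucleic acids)
929	EVs	Left-handed helix DNA (Z-form)
923	cells	Left-handed helix DNA (Z-form)
915	EVs	Ribose ring vibrations (nucleic acids)
903	cells	Ribose ring vibrations (nucleic acids)	interpolated from neighbouring band 915
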