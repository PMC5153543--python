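item_name,dosage,unit_price,category
Acyclovir,,0.0468,oi_drug
Amoxycillin,,0.0057,oi_drug
Ampicillin,,0.098,oi_drug
Benzyl Penicillin,,0.022716,oi_drug
Brufen,,0.0042,oi_drug
Ceftriaxone,,0.5156,oi_drug
Cephalexin,,0.0468,oi_drug
Cetirizine,,0.018,oi_drug
Chlorpheniramine,,0.0017,oi_drug
Chloramphenicol,,0.45,oi_drug
Ciprofloxacin,,0.0257,oi_drug
Cloxacillin,,0.0551,oi_drug
Coartem,,0.0268,oi_drug
Cotrimoxazole,,0.2,oi_drug
Erythromycin,,0.0532,oi_drug
Augmentin,,0.687,oi_drug
Fansidar,,0.0173,oi_drug
Ferrous sulphate,,0.0052,oi_drug
Flagyl,,0.0395,oi_drug
Fluconazole,,0.1455,oi_drug
Folic acid,,0.0024,oi_drug
Frusemide,,0.0494,oi_drug
Gentamycin,,0.0024,oi_drug
Griseofulvin,,0.0042,oi_drug
Isoniazid,,0.1032,oi_drug
Ketoconazole,,0.0024,oi_drug
Mebendazole,,0.0178,oi_drug
Nalidixic acid,,0.0438,oi_drug
Panadol,,0.0024,oi_drug
Paracetamol,,0.0255,oi_drug
Penicillin V,,0.0071,oi_drug
Piriton,,0.0017,oi_drug
Prednisolone,,0.0762,oi_drug
Procaine penicillin,,0.822,oi_drug
Promethazine,,0.0061,oi_drug
Pyrazinamide,,0.1774,oi_drug
Quinine,,0.1032,oi_drug
Rifampicin,,0.1032,oi_drug
Salbutamol,,0.0045,oi_drug
Xpen,,0.255,oi_drug
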