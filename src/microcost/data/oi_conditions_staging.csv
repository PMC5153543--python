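condition,frequency,printed_percent
Papular pruritic eruptions,1,0.13
Extensive molluscum contagiosum,1,0.13
Recurrent oral ulcerations (2 or more episodes in 6 months),1,0.13
Unexplained persistent parotid enlargement,2,0.27
"Recurrent or chronic upper respiratory tract infections (otitis media, otorrhoea, sinusitis, tonsillitis)",1,0.13
Moderate unexplained malnutrition not adequately responding to standard therapy,83,11.05
Unexplained persistent diarrhoea (>14 days),163,21.7
"Unexplained persistent fever (above 37.5 intermittent or constant, for >1 month)",176,23.44
Persistent oral candidiasis (outside neonatal period),74,9.85
Oral hairy leukoplakia,1,0.13
Acute necrotizing ulcerative gingivitis/periodontitis,1,0.13
Pulmonary tuberculosis,70,9.32
Severe recurrent presumed bacterial pneumonia,79,10.52
"Unexplained anaemia (<8 gm/dL), neutropenia (<500/mm3), or thrombocytopenia (<50,000/mm3) for > 1 month",10,1.33
Symptomatic lymphoid interstitial pneumonia (LIP),4,0.53
TB lymphadenitis,1,0.13
Unexplained severe wasting or severe malnutrition not adequately responding to therapy,72,9.59
Recurrent severe presumed bacterial infections,1,0.13
"Chronic herpes simplex infection (orolabial or cutaneous, for >1 month, visceral at any site)",1,0.13
Extrapulmonary TB,5,0.67
Kaposi's sarcoma,2,0.27
"Oesophageal candidiasis (or candida of trachea, bronchi, or lungs)",1,0.13
Extrapulmonary cryptococcosis including meningitis,1,0.13
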