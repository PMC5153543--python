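condition,frequency,printed_percent
Abscess/diarrhoea,1,0.26
Abscess/pneumonia,1,0.26
Anaemia,2,0.52
Anaemia/TB,2,0.52
Bronchitis/empyema,1,0.26
Bronchitis/pneumonia,1,0.26
Cellulitis pneumonia,1,0.26
Chicken pox,3,0.78
Conjunctivitis/marasmus/diarrhoea,1,0.26
Diarrhoea,12,3.1
Diarrhoea/abscess/TB/bronchitis,3,0.78
Diarrhoea/kwashiorkor/paronychia,2,0.52
Diarrhoea/lymphadenopathy,1,0.26
Diarrhoea/malaria,1,0.26
Diarrhoea/pneumonia/malaria/lymphadenopathy,1,0.26
Diarrhoea/pneumonia/marasmus/kwashiorkor/TB,10,2.6
Diarrhoea/TB,4,1.04
Eczema/pneumonia,1,0.26
Fevers/measles/TB/pneumonia,4,1.04
Gastroenteritis/dysentery/gastritis,7,1.82
Herpes simplex,1,0.26
Herpes zoster/pneumonia,3,0.78
Lymphadenopathy/parotitis,5,1.3
Malaria,9,2.33
Malaria/anaemia/diarrhoea/malnutrition/TB/marasmus/meningitis/pneumonia,18,4.68
Malnutrition/TB/measles/marasmus/chicken pox/diarrhoea,17,4.42
Marasmus/kwashiorkor,2,0.52
Marasmus/kwashiorkor/diarrhoea/dehydration,1,0.26
Marasmus/kwashiorkor/pneumonia/TB,10,2.6
Measles,4,1.03
Measles/pneumonia,2,0.52
Meningitis/malaria/pneumonia/otitis media pneumonia,15,3.89
Pleural effusion,1,0.26
Pneumonia,49,12.74
Pneumonia/abscess/malaria/TB/fever/kwashiokor/measles/ari/septecemia,27,7.02
Pneumonia/anaemia,44,11.44
RTI,20,5.2
Septic arthritis,1,0.26
Septicaemia,1,0.26
Septicaemia/meningitis,1,0.26
Septicaemia/meningitis/pneumonia/TB,1,0.26
TB,75,19.5
TB/diarrhoea/malnutrition/thrush/meningitis/neutritis/tonsilities,15,3.9
Unknown,3,0.78
Chicken pox (second listing),1,0.26
UTI,1,0.26
UTI/oral thrush,1,0.26
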