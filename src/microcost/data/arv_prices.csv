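item_name,dosage,unit_price,category
Lamivir Baby,0.3 g,0.0313,arv
Lamivir Junior,0.3 g,0.0587,arv
Efavirenz,0.6 g,0.154,arv
Pedimune Baby,0.6 g,0.023,arv
Pedimune Junior,0.8 g,0.006,arv
Triomune,0.3 g,0.058,arv
Lamivudine,0.3 g,0.006,arv
Stavudine,0.8 g,0.023,arv
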