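scat_id,predator,prey_taxon
L01,leopard,Potamochoerus porcus
L02,leopard,Potamochoerus porcus
L03,leopard,Potamochoerus porcus
L04,leopard,Potamochoerus porcus
L05,leopard,Potamochoerus porcus
L06,leopard,Cephalophus sylvicultor
L07,leopard,Colobus guereza
L08,leopard,Lophocebus albigena
L09,leopard,Cephalophus callipygus
L09,leopard,Cercopithecus pogonias
L09,leopard,Civettictis civetta
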