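taxon,abm_kg,group
Cephalophus callipygus,20.8,ungulates
Cephalophus sp.,19.2,ungulates
Cephalophus sylvicultor,69.2,ungulates
Philantomba monticola,5.1,ungulates
Potamochoerus porcus,53.3,ungulates
Cercopithecus nictitans,5.4,primates
Cercopithecus pogonias,3.7,primates
Colobus guereza,8.4,primates
Lophocebus albigena,7.7,primates
Atherurus africanus,3.0,rodents
Cricetomys emini,0.9,rodents
Murinae,0.25,rodents
Civettictis civetta,12.6,carnivores
Genetta servalina,2.3,carnivores
Birds,0.5,birds
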