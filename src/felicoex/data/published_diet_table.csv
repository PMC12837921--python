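predator,taxon,abm_kg,group,fo,cfo,rbc
leopard,Cephalophus callipygus,20.8,ungulates,11.1,3.7,3.8
leopard,Cephalophus sylvicultor,69.2,ungulates,11.1,11.1,12.4
leopard,Potamochoerus porcus,53.3,ungulates,55.6,55.6,61.8
leopard,Cercopithecus pogonias,3.7,primates,11.1,3.7,2.1
leopard,Colobus guereza,8.4,primates,11.1,11.1,8.5
leopard,Lophocebus albigena,7.7,primates,11.1,11.1,8.2
leopard,Civettictis civetta,12.6,carnivores,11.1,3.7,3.3
golden_cat,Cephalophus callipygus,20.8,ungulates,12.5,9.4,13.6
golden_cat,Cephalophus sp.,19.2,ungulates,6.3,3.1,4.5
golden_cat,Philantomba monticola,5.1,ungulates,31.3,25.0,33.9
golden_cat,Cercopithecus nictitans,5.4,primates,6.3,6.3,8.6
golden_cat,Atherurus africanus,3.0,rodents,6.3,6.3,7.5
golden_cat,Cricetomys emini,0.9,rodents,12.5,9.4,7.1
golden_cat,Murinae,0.25,rodents,43.8,31.3,16.0
golden_cat,Genetta servalina,2.3,carnivores,6.3,6.3,6.8
golden_cat,Birds,0.5,birds,6.3,3.1,1.9
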