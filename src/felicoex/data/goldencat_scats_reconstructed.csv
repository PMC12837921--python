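scat_id,predator,prey_taxon
G01,golden_cat,Cephalophus callipygus
G02,golden_cat,Philantomba monticola
G03,golden_cat,Philantomba monticola
G04,golden_cat,Philantomba monticola
G05,golden_cat,Cercopithecus nictitans
G06,golden_cat,Atherurus africanus
G07,golden_cat,Cricetomys emini
G08,golden_cat,Murinae
G09,golden_cat,Murinae
G10,golden_cat,Genetta servalina
G11,golden_cat,Murinae
G11,golden_cat,Murinae
G12,golden_cat,Murinae
G12,golden_cat,Cephalophus callipygus
G13,golden_cat,Murinae
G13,golden_cat,Cephalophus sp.
G14,golden_cat,Murinae
G14,golden_cat,Philantomba monticola
G15,golden_cat,Murinae
G15,golden_cat,Cricetomys emini
G16,golden_cat,Birds
G16,golden_cat,Philantomba monticola
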