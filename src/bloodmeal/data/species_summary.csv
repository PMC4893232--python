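mosquito_taxon,n_specimens,pct_all_specimens,birds,non_human_mammals,humans,n_host_species,is_aggregate
Aedes albopictus,1,0.1,0,0,1,1,0
Aedes cinereus,25,3.2,2,19,4,9,0
Aedes rossicus,42,5.4,0,37,5,5,0
Aedes vexans,363,46.8,4,325,34,21,0
Aedes/Ochlerotatus spp.,15,1.9,0,14,1,4,1
Anopheles claviger,11,1.4,0,7,4,5,0
Anopheles maculipennis (s.l.),10,1.3,1,9,0,6,0
Anopheles plumbeus,1,0.1,0,0,1,1,0
Coquillettidia richiardii,11,1.4,0,10,1,5,0
Culiseta annulata,18,2.3,0,14,4,5,0
Culiseta morsitans,18,2.3,2,5,11,4,0
Culex pipiens pipiens form pipiens,100,12.9,28,37,35,15,0
Culex pipiens (s.l.)/torrentium,10,1.3,4,0,6,2,1
Culex spp.,1,0.1,1,0,0,1,1
Culex torrentium,15,1.9,8,1,6,3,0
Ochlerotatus annulipes,8,1.0,0,3,5,3,0
Ochlerotatus cantans,99,12.8,0,73,26,5,0
Ochlerotatus cantans/annulipes,2,0.3,0,1,1,2,1
Ochlerotatus communis,3,0.4,0,2,1,2,0
Ochlerotatus excrucians,1,0.1,0,0,1,1,0
Ochlerotatus geniculatus,2,0.3,0,0,2,1,0
Ochlerotatus refiki,1,0.1,0,0,1,1,0
Ochlerotatus rusticus,2,0.3,0,2,0,2,0
Ochlerotatus sticticus,16,2.1,1,13,2,7,0
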