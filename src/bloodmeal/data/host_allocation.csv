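# Synthetic reconstruction: a per-(mosquito taxon, host species) count table consistent
# with the published per-taxon host-group counts, per-taxon distinct-host-species counts,
# per-host-species totals and host-range breadths. The true specimen-level allocation was
# never published; this is one feasible solution, fixed for reproducible analyses.
mosquito_taxon,host_species,count
Aedes albopictus,Homo sapiens,1
Aedes cinereus,Turdus merula,1
Aedes cinereus,Sylvia communis,1
Aedes cinereus,Rattus norvegicus,1
Aedes cinereus,Ovis aries,2
Aedes cinereus,Lepus europaeus,2
Aedes cinereus,Capreolus capreolus,8
Aedes cinereus,Bos taurus,3
Aedes cinereus,Sus scrofa,3
Aedes cinereus,Homo sapiens,4
Aedes rossicus,Ovis aries,2
Aedes rossicus,Capreolus capreolus,20
Aedes rossicus,Bos taurus,5
Aedes rossicus,Sus scrofa,10
Aedes rossicus,Homo sapiens,5
Aedes vexans,Turdus merula,1
Aedes vexans,Sylvia communis,1
Aedes vexans,Anas platyrhynchus,1
Aedes vexans,Corvus corone,1
Aedes vexans,Felis catus,3
Aedes vexans,Vulpes vulpes,3
Aedes vexans,Castor fiber,2
Aedes vexans,Microtus guentheri,2
Aedes vexans,Myotis spp.,2
Aedes vexans,Canis lupus familiaris,1
Aedes vexans,Capra hircus,1
Aedes vexans,Erinaceus europaeus,1
Aedes vexans,Equus caballus,2
Aedes vexans,Oryctolagus cuniculus,6
Aedes vexans,Cervus elaphus,4
Aedes vexans,Ovis aries,9
Aedes vexans,Lepus europaeus,8
Aedes vexans,Capreolus capreolus,150
Aedes vexans,Bos taurus,57
Aedes vexans,Sus scrofa,74
Aedes vexans,Homo sapiens,34
Aedes/Ochlerotatus spp.,Ovis aries,6
Aedes/Ochlerotatus spp.,Lepus europaeus,5
Aedes/Ochlerotatus spp.,Cervus elaphus,3
Aedes/Ochlerotatus spp.,Homo sapiens,1
Anopheles claviger,Lepus europaeus,1
Anopheles claviger,Capreolus capreolus,3
Anopheles claviger,Bos taurus,2
Anopheles claviger,Sus scrofa,1
Anopheles claviger,Homo sapiens,4
Anopheles maculipennis (s.l.),Turdus merula,1
Anopheles maculipennis (s.l.),Cervus elaphus,2
Anopheles maculipennis (s.l.),Ovis aries,2
Anopheles maculipennis (s.l.),Lepus europaeus,2
Anopheles maculipennis (s.l.),Capreolus capreolus,2
Anopheles maculipennis (s.l.),Bos taurus,1
Anopheles plumbeus,Homo sapiens,1
Coquillettidia richiardii,Equus caballus,4
Coquillettidia richiardii,Oryctolagus cuniculus,2
Coquillettidia richiardii,Capreolus capreolus,2
Coquillettidia richiardii,Bos taurus,2
Coquillettidia richiardii,Homo sapiens,1
Culiseta annulata,Ovis aries,1
Culiseta annulata,Capreolus capreolus,8
Culiseta annulata,Bos taurus,3
Culiseta annulata,Sus scrofa,2
Culiseta annulata,Homo sapiens,4
Culiseta morsitans,Emberiza citrinella,2
Culiseta morsitans,Capreolus capreolus,3
Culiseta morsitans,Sus scrofa,2
Culiseta morsitans,Homo sapiens,11
Culex pipiens pipiens form pipiens,Turdus merula,9
Culex pipiens pipiens form pipiens,Turdus philomelos,7
Culex pipiens pipiens form pipiens,Cyanistes caeruleus,4
Culex pipiens pipiens form pipiens,Passer domesticus,3
Culex pipiens pipiens form pipiens,Sylvia atricapilla,3
Culex pipiens pipiens form pipiens,Delichon urbica,2
Culex pipiens pipiens form pipiens,Lama pacos,1
Culex pipiens pipiens form pipiens,Myocastor coypus,1
Culex pipiens pipiens form pipiens,Myodes glareolus,1
Culex pipiens pipiens form pipiens,Ovis aries,3
Culex pipiens pipiens form pipiens,Lepus europaeus,3
Culex pipiens pipiens form pipiens,Capreolus capreolus,14
Culex pipiens pipiens form pipiens,Bos taurus,8
Culex pipiens pipiens form pipiens,Sus scrofa,6
Culex pipiens pipiens form pipiens,Homo sapiens,35
Culex pipiens (s.l.)/torrentium,Turdus merula,4
Culex pipiens (s.l.)/torrentium,Homo sapiens,6
Culex spp.,Turdus merula,1
Culex torrentium,Turdus merula,8
Culex torrentium,Bos taurus,1
Culex torrentium,Homo sapiens,6
Ochlerotatus annulipes,Capreolus capreolus,2
Ochlerotatus annulipes,Oryctolagus cuniculus,1
Ochlerotatus annulipes,Homo sapiens,5
Ochlerotatus cantans,Lepus europaeus,3
Ochlerotatus cantans,Capreolus capreolus,40
Ochlerotatus cantans,Bos taurus,15
Ochlerotatus cantans,Sus scrofa,15
Ochlerotatus cantans,Homo sapiens,26
Ochlerotatus cantans/annulipes,Ovis aries,1
Ochlerotatus cantans/annulipes,Homo sapiens,1
Ochlerotatus communis,Capreolus capreolus,2
Ochlerotatus communis,Homo sapiens,1
Ochlerotatus excrucians,Homo sapiens,1
Ochlerotatus geniculatus,Homo sapiens,2
Ochlerotatus refiki,Homo sapiens,1
Ochlerotatus rusticus,Bos taurus,1
Ochlerotatus rusticus,Sus scrofa,1
Ochlerotatus sticticus,Erithacus rubecula,1
Ochlerotatus sticticus,Ovis aries,2
Ochlerotatus sticticus,Lepus europaeus,2
Ochlerotatus sticticus,Capreolus capreolus,4
Ochlerotatus sticticus,Bos taurus,3
Ochlerotatus sticticus,Sus scrofa,2
Ochlerotatus sticticus,Homo sapiens,2
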