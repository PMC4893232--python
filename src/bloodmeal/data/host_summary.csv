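host_species,host_group,n_specimens,pct_all_specimens
Anas platyrhynchus,bird,1,0.1
Corvus corone,bird,1,0.1
Cyanistes caeruleus,bird,4,0.5
Delichon urbica,bird,2,0.3
Emberiza citrinella,bird,2,0.3
Erithacus rubecula,bird,1,0.1
Passer domesticus,bird,3,0.4
Sylvia atricapilla,bird,3,0.4
Sylvia communis,bird,2,0.3
Turdus merula,bird,25,3.2
Turdus philomelos,bird,7,0.9
Homo sapiens,human,152,19.6
Bos taurus,non-human mammal,101,13.0
Canis lupus familiaris,non-human mammal,1,0.1
Capra hircus,non-human mammal,1,0.1
Capreolus capreolus,non-human mammal,258,33.3
Castor fiber,non-human mammal,2,0.3
Cervus elaphus,non-human mammal,9,1.2
Equus caballus,non-human mammal,6,0.8
Erinaceus europaeus,non-human mammal,1,0.1
Felis catus,non-human mammal,3,0.4
Lama pacos,non-human mammal,1,0.1
Lepus europaeus,non-human mammal,26,3.4
Microtus guentheri,non-human mammal,2,0.3
Myocastor coypus,non-human mammal,1,0.1
Myodes glareolus,non-human mammal,1,0.1
Myotis spp.,non-human mammal,2,0.3
Oryctolagus cuniculus,non-human mammal,9,1.2
Ovis aries,non-human mammal,28,3.6
Rattus norvegicus,non-human mammal,1,0.1
Sus scrofa,non-human mammal,116,15.0
Vulpes vulpes,non-human mammal,3,0.4
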