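mosquito_taxon,period,host_group,n_specimens,pct_within_species_period
Aedes vexans,early,bird,1,1.5
Aedes vexans,early,human,1,1.5
Aedes vexans,early,non-human mammal,63,96.9
Aedes vexans,late,bird,3,1.0
Aedes vexans,late,human,33,11.1
Aedes vexans,late,non-human mammal,262,87.9
Culex pipiens pipiens form pipiens,early,bird,3,21.4
Culex pipiens pipiens form pipiens,early,human,5,35.7
Culex pipiens pipiens form pipiens,early,non-human mammal,6,42.9
Culex pipiens pipiens form pipiens,late,bird,25,29.1
Culex pipiens pipiens form pipiens,late,human,30,34.9
Culex pipiens pipiens form pipiens,late,non-human mammal,31,36.0
Ochlerotatus cantans,early,bird,0,0
Ochlerotatus cantans,early,human,19,27.1
Ochlerotatus cantans,early,non-human mammal,51,72.9
Ochlerotatus cantans,late,bird,0,0
Ochlerotatus cantans,late,human,7,24.1
Ochlerotatus cantans,late,non-human mammal,22,75.9
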