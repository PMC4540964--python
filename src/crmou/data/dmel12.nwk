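((((((Dmel:5.4,(Dsim:2.3,Dsec:2.3):3.1):7.2,(Dyak:11.0,Dere:11.0):1.6):31.6,Dana:44.2):10.7,(Dpse:1.0,Dper:1.0):53.9):7.3,Dwil:62.2):0.8,((Dmoj:32.0,Dvir:32.0):10.0,Dgri:42.0):21.0);
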