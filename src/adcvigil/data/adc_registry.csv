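drug_name,antibody,linker,payload,dar_value,dar_class,include,aliases
gemtuzumab ozogamicin,IgG4,cleavable,dna_damaging,2.5,lt3,1,mylotarg
brentuximab vedotin,IgG1,cleavable,microtubule_inhibitor,4.0,3to5,1,adcetris
ado-trastuzumab emtansine,IgG1,non_cleavable,microtubule_inhibitor,3.5,3to5,1,kadcyla;trastuzumab emtansine
inotuzumab ozogamicin,IgG4,cleavable,dna_damaging,6.0,gt5,1,besponsa
moxetumomab pasudotox,IgG1,cleavable,other,,lt3,1,lumoxiti;moxetumomab pasudotox-tdfk
polatuzumab vedotin,IgG1,cleavable,microtubule_inhibitor,3.5,3to5,1,polivy;polatuzumab vedotin-piiq
enfortumab vedotin,IgG1,cleavable,microtubule_inhibitor,3.8,3to5,1,padcev;enfortumab vedotin-ejfv
fam-trastuzumab deruxtecan,IgG1,cleavable,dna_damaging,8.0,gt5,1,enhertu;trastuzumab deruxtecan;fam-trastuzumab deruxtecan-nxki
sacituzumab govitecan,IgG1,cleavable,dna_damaging,7.6,gt5,1,trodelvy;sacituzumab govitecan-hziy
belantamab mafodotin,IgG1,non_cleavable,microtubule_inhibitor,4.0,3to5,1,blenrep;belantamab mafodotin-blmf
loncastuximab tesirine,IgG1,cleavable,dna_damaging,2.3,lt3,1,zynlonta;loncastuximab tesirine-lpyl
tisotumab vedotin,IgG1,cleavable,microtubule_inhibitor,4.0,3to5,1,tivdak;tisotumab vedotin-tftv
mirvetuximab soravtansine,IgG1,cleavable,microtubule_inhibitor,3.4,3to5,1,elahere;mirvetuximab soravtansine-gynx
datopotamab deruxtecan,IgG1,cleavable,dna_damaging,4.0,3to5,0,datroway;datopotamab deruxtecan-dlnk
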