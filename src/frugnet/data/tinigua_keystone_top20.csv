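pulp_species,pulp_flow_g_ha_day,scarcity_species,scarcity_keystone_index
Pseudolmedia laevis,16938,Oenocarpus bataua,7.32
Pseudolmedia hirsuta,11942,Cecropia membranacea,6.36
Pseudolmedia laevigata,8709,Bursera inversa,5.90
Spondias venulosa,3848,Ficus davidsoni,5.41
Oxandra mediocris,2660,Gustavia hexapetala,4.80
Crepidospermum rhoifolium,2578,Brosimum alicastrum,4.51
Talisia intermedia,2182,Ficus sphenophylla,4.48
Socratea exorrhiza,1999,Brosimum guianense,4.31
Alibertia cf. hadrantha,1705,Iriartea deltoidea,4.26
Oenocarpus bataua,1674,Astrocaryum chambira,3.98
Protium glabrescens,1208,Apeiba aspera,3.79
Inga acreana,1174,Pseudolmedia hirsuta,3.77
Garcinia macrophylla,997,Brosimum utile,3.77
Gustavia hexapetala,966,Ficus americana,3.72
Protium sagotianum,938,Dialium guianense,3.58
Coussapoa orthoneura,920,Henriettella fissanthera,3.28
Spondias mombin,891,Ficus trigonata,3.16
Castilla ulei,748,Pourouma bicolor,3.07
Cecropia membranacea,652,Enterolobium schomburgkii,2.72
Brosimum lactescens,586,Ficus trigona,2.53
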