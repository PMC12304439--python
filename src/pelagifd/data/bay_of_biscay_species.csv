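order,family,species,depth_min_m,depth_max_m,n_individuals,sl_mean_cm,sl_sd_cm
Myctophiformes,Myctophidae,Benthosema glaciale,20,2000,20,4.3,0.2
Myctophiformes,Myctophidae,Bolinichthys supralateralis,735,1335,11,9.6,0.6
Myctophiformes,Myctophidae,Ceratoscopelus maderensis,20,2000,30,6.3,0.7
Myctophiformes,Myctophidae,Diaphus metopoclampus,735,2000,4,6.1,1.7
Myctophiformes,Myctophidae,Lampanyctus ater,200,2000,22,10.9,1.1
Myctophiformes,Myctophidae,Lampanyctus crocodilus,300,2000,39,10.8,1.7
Myctophiformes,Myctophidae,Lampanyctus macdonaldi,1000,2000,21,12.9,0.6
Myctophiformes,Myctophidae,Lobianchia gemellarii,30,2000,22,8.3,0.7
Myctophiformes,Myctophidae,Myctophum punctatum,20,2000,25,6.5,0.8
Myctophiformes,Myctophidae,Notoscopelus bolini,20,1335,20,7.6,0.4
Myctophiformes,Myctophidae,Notoscopelus kroyeri,20,2000,36,7.6,1.6
Alepocephaliformes,Platytroctidae,Holtbyrnia anomala,1500,1600,3,6.6,0.7
Alepocephaliformes,Platytroctidae,Holtbyrnia macrops,500,1500,9,7.9,2.3
Alepocephaliformes,Platytroctidae,Maulisia argipalla,730,1600,5,9.5,1.9
Alepocephaliformes,Platytroctidae,Maulisia mauli,685,1600,11,11.7,2.8
Alepocephaliformes,Platytroctidae,Maulisia microlepis,1000,2000,4,23.1,2.2
Alepocephaliformes,Platytroctidae,Normichthys operosus,1000,2000,38,10.5,1.8
Alepocephaliformes,Platytroctidae,Sagamichthys schnakenbecki,300,1500,9,9.2,2.1
Alepocephaliformes,Platytroctidae,Searsia koefoedi,480,2000,36,12.0,1.4
Alepocephaliformes,Alepocephalidae,Photostylus pycnopterus,1000,1600,8,9.6,1.5
Alepocephaliformes,Alepocephalidae,Xenodermichthys copei,200,2000,38,11.0,1.2
Stomiiformes,Stomiidae,Borostomias antarcticus,600,2000,14,12.2,5.6
Stomiiformes,Stomiidae,Chauliodus sloani,200,2000,12,22.9,5.9
Stomiiformes,Stomiidae,Malacosteus niger,510,2000,5,15.7,4.1
Stomiiformes,Stomiidae,Melanostomias bartonbeani,20,2000,9,23.3,2.5
Stomiiformes,Stomiidae,Stomias boa,20,2000,26,23.9,4.5
Stomiiformes,Gonostomatidae,Cyclothone microdon,200,2000,12,5.3,0.6
Stomiiformes,Gonostomatidae,Gonostoma elongatum,735,1010,3,23.6,1.4
Stomiiformes,Gonostomatidae,Sigmops bathyphilus,1000,2000,20,9.2,1.8
Stomiiformes,Sternoptychidae,Argyropelecus hemigymnus,150,2000,17,3.1,0.4
Stomiiformes,Sternoptychidae,Argyropelecus olfersii,150,2000,37,5.7,1.1
Stomiiformes,Sternoptychidae,Maurolicus muelleri,20,2000,11,3.2,0.2
Aulopiformes,Paralepididae,Arctozenus risso,150,2000,30,15.8,1.5
Aulopiformes,Paralepididae,Paralepis coregonoides,500,1600,19,7.3,1.5
Aulopiformes,Evermannellidae,Evermannella balbo,555,1500,4,10.5,0.3
Aulopiformes,Lestidiidae,Lestidiops sphyrenoides,20,1335,7,14.8,0.9
Anguilliformes,Derichthyidae,Derichthys serpentinus,500,1600,7,22.6,3.3
Anguilliformes,Serrivomeridae,Serrivomer beanii,200,2000,30,54.6,12.1
Argentiniformes,Bathylagidae,Bathylagus euryops,1335,2000,19,12.3,3.6
Perciformes,Zoarcidae,Melanostigma atlanticum,555,1600,20,8.4,1.1
Saccopharyngiformes,Eurypharyngidae,Eurypharynx pelecanoides,1300,2000,6,36.5,6.5
Trachichthyiformes,Anoplogastridae,Anoplogaster cornuta,1000,1600,3,13.0,1.7
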