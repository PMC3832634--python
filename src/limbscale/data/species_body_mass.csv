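species,common_name,order,n_specimens,body_mass_g,specialization,source
Didelphis_virginiana,Virginia opossum,Didelphimorphia,3,3240,scansorial,literature
Canis_latrans,Coyote,Carnivora,2,11488,cursorial,literature
Canis_lupus,Gray wolf,Carnivora,7,30773,cursorial,literature
Lycaon_pictus,African hunting dog,Carnivora,1,22050,cursorial,literature
Otocyon_megalotis,Bat-eared fox,Carnivora,1,3000,cursorial,literature
Urocyon_cinereoargenteus,Gray fox,Carnivora,4,3745,cursorial,literature
Vulpes_vulpes,Red fox,Carnivora,1,3587,cursorial,literature
Acinonyx_jubatus,Cheetah,Carnivora,1,50000,cursorial,literature
Caracal_caracal,Caracal,Carnivora,3,7050,,literature
Leptailurus_serval,Serval,Carnivora,1,10500,,synthetic_fill
Lynx_rufus,Bobcat,Carnivora,4,8960,cursorial,literature
Puma_concolor,Mountain lion,Carnivora,1,68039,cursorial,literature
Mephitis_mephitis,Striped skunk,Carnivora,1,2386,generalist,literature
Lontra_canadensis,N. American river otter,Carnivora,5,7287,natatorial,literature
Martes_pennanti,Fisher,Carnivora,5,4662,scansorial,literature
Mellivora_capensis,Ratel,Carnivora,2,15100,fossorial,literature
Taxidea_taxus,N. American badger,Carnivora,4,6173,fossorial,literature
Procyon_lotor,Raccoon,Carnivora,5,6179,scansorial,literature
Aepyceros_melampus,Impala,Artiodactyla,2,51750,cursorial,literature
Antidorcas_marsupialis,Springbok,Artiodactyla,3,39050,cursorial,literature
Connochaetes_gnou,Black wildebeest,Artiodactyla,1,107450,cursorial,literature
Kobus_ellipsiprymnus,Waterbuck,Artiodactyla,2,238000,cursorial,literature
Oreotragus_oreotragus,Klipspringer,Artiodactyla,2,10500,cursorial,literature
Raphicerus_melanotis,Grysbok,Artiodactyla,1,9750,cursorial,literature
Tragelaphus_scriptus,Bushbuck,Artiodactyla,1,54000,cursorial,literature
Tragelaphus_strepsiceros,Greater kudu,Artiodactyla,2,236500,cursorial,literature
Cervus_canadensis,Elk,Artiodactyla,5,241500,cursorial,literature
Cervus_elaphus,Red deer,Artiodactyla,1,166563,,literature
Odocoileus_virginianus,White-tailed deer,Artiodactyla,4,69318,cursorial,literature
Okapia_johnstoni,Okapi,Artiodactyla,1,230001,cursorial,literature
Dasypus_novemcinctus,Nine-banded armadillo,Cingulata,2,4904,fossorial,literature
Procavia_capensis,Rock hyrax,Hyracoidea,1,2250,scansorial,literature
Sylvilagus_floridanus,Eastern cottontail,Lagomorpha,3,1131,cursorial,literature
Equus_caballus,Domestic horse,Perissodactyla,4,446250,cursorial,literature
Equus_quagga_burchellii,Burchell's zebra,Perissodactyla,2,266675,,literature
Castor_canadensis,N. American beaver,Rodentia,5,16810,natatorial,literature
Erethizon_dorsatum,N. American porcupine,Rodentia,1,5540,scansorial,literature
Hystrix_africaeaustralis,Cape porcupine,Rodentia,2,14936,fossorial,literature
Ondatra_zibethicus,Muskrat,Rodentia,4,1061,natatorial,literature
Rattus_rattus,Black rat,Rodentia,4,331,generalist,literature
Marmota_monax,Woodchuck,Rodentia,2,3542,fossorial,literature
Sciurus_carolinensis,Gray squirrel,Rodentia,4,528,scansorial,literature
Sciurus_niger,Fox squirrel,Rodentia,2,666,scansorial,literature
Tamias_striatus,Eastern chipmunk,Rodentia,4,97,generalist,literature
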