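(Didelphis_virginiana:160,((Dasypus_novemcinctus:95,Procavia_capensis:95):5,((Sylvilagus_floridanus:80,((Marmota_monax:40,(Tamias_striatus:30,(Sciurus_carolinensis:10,Sciurus_niger:10):20):10):30,(Castor_canadensis:65,((Rattus_rattus:30,Ondatra_zibethicus:30):30,(Hystrix_africaeaustralis:45,Erethizon_dorsatum:45):15):5):5):10):10,(((((Acinonyx_jubatus:10,Puma_concolor:10):5,(Lynx_rufus:12,(Caracal_caracal:8,Leptailurus_serval:8):4):3):35):10,((((Canis_latrans:3,Canis_lupus:3):7,Lycaon_pictus:10):2,(Otocyon_megalotis:11,(Vulpes_vulpes:9,Urocyon_cinereoargenteus:9):2):1):33,(Mephitis_mephitis:40,(Procyon_lotor:35,(Martes_pennanti:20,(Mellivora_capensis:15,(Taxidea_taxus:12,Lontra_canadensis:12):3):5):15):5):5):15):25,((Equus_caballus:4,Equus_quagga_burchellii:4):71,((Okapia_johnstoni:28,(Odocoileus_virginianus:20,(Cervus_canadensis:5,Cervus_elaphus:5):15):8):32,(((Tragelaphus_scriptus:8,Tragelaphus_strepsiceros:8):7,(Kobus_ellipsiprymnus:12,(Connochaetes_gnou:10,Aepyceros_melampus:10):2):3):7,(Antidorcas_marsupialis:14,(Oreotragus_oreotragus:10,Raphicerus_melanotis:10):4):8):38):15):10):5):10):60);
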