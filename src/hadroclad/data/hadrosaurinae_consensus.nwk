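(Hadrosaurus_foulkii,(Wulagasaurus_dongi,(Acristavus_gagslarsoni,(Maiasaura_peeblesorum,(Brachylophosaurus_canadensis,Probrachylophosaurus_bergei)))),(((Gryposaurus_notabilis,(Gryposaurus_monumentensis,(Gryposaurus_latidens,Rhinorex_condrupus))),(Kritosaurus_navajovius,(Secernosaurus_koerneri,Willinakaqe_salitralensis))),((Lophorhothon_atopus,(Prosaurolophus_maximus,(Saurolophus_osborni,Saurolophus_angustirostris))),(Kerberosaurus_manakini,(Shantungosaurus_giganteus,(Edmontosaurus_regalis,Edmontosaurus_annectens))))));
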