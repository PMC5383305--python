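# Continental region of fossil occurrence per hadrosaurine terminal.
# Kerberosaurus manakini subsumes its junior synonym Kundurosaurus nagornyi
# (one Asian terminal). Editable: replace rows to change tip assignments.
taxon	area
Hadrosaurus_foulkii	NorthAmerica
Wulagasaurus_dongi	Asia
Acristavus_gagslarsoni	NorthAmerica
Maiasaura_peeblesorum	NorthAmerica
Brachylophosaurus_canadensis	NorthAmerica
Probrachylophosaurus_bergei	NorthAmerica
Gryposaurus_notabilis	NorthAmerica
Gryposaurus_monumentensis	NorthAmerica
Gryposaurus_latidens	NorthAmerica
Rhinorex_condrupus	NorthAmerica
Kritosaurus_navajovius	NorthAmerica
Secernosaurus_koerneri	SouthAmerica
Willinakaqe_salitralensis	SouthAmerica
Lophorhothon_atopus	NorthAmerica
Prosaurolophus_maximus	NorthAmerica
Saurolophus_osborni	NorthAmerica
Saurolophus_angustirostris	Asia
Kerberosaurus_manakini	Asia
Shantungosaurus_giganteus	Asia
Edmontosaurus_regalis	NorthAmerica
Edmontosaurus_annectens	NorthAmerica
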