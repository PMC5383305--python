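# SYNTHETIC stage-level stratigraphic ranges (Ma, GTS 2009 boundaries) for the
# hadrosaurine fixture. Built from stage placements stated in the literature
# (e.g. Hadrosaurus foulkii and Lophorhothon atopus in lower Campanian
# exposures of Appalachia); these are reconstructed stand-ins, not the exact
# published FAD/LAD compilation. Editable: replace rows with measured values.
taxon	fad_Ma	lad_Ma
Hadrosaurus_foulkii	83.5	78.0
Wulagasaurus_dongi	69.0	66.0
Acristavus_gagslarsoni	81.0	75.0
Maiasaura_peeblesorum	77.0	75.0
Brachylophosaurus_canadensis	78.0	75.0
Probrachylophosaurus_bergei	80.0	79.0
Gryposaurus_notabilis	77.0	74.0
Gryposaurus_monumentensis	76.0	74.0
Gryposaurus_latidens	81.0	79.0
Rhinorex_condrupus	76.0	74.0
Kritosaurus_navajovius	75.0	70.6
Secernosaurus_koerneri	70.6	66.0
Willinakaqe_salitralensis	73.0	68.0
Lophorhothon_atopus	83.5	79.0
Prosaurolophus_maximus	76.0	73.0
Saurolophus_osborni	70.6	68.0
Saurolophus_angustirostris	70.6	66.0
Kerberosaurus_manakini	68.0	66.0
Shantungosaurus_giganteus	77.0	73.0
Edmontosaurus_regalis	73.0	71.0
Edmontosaurus_annectens	68.0	66.0
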