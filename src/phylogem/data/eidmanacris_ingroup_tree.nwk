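((E_fusca,(E_melloi,(E_endophallica,E_minuta)))A,(E_bidentata,(E_putuhra,((E_tridentata,(E_simoesi,E_eliethae))G,(E_papaveroi,(E_fontanettiae,((E_larvaeformis,(E_septentrionalis,(E_speluncae,E_multispinosa)))M,(((E_dissimilis,E_meridionalis),(E_alboannulata,E_suassunai))N1,(E_scopula,(E_desutterae,((E_corumbatai,E_gigas),(E_caipira,(E_bernardii,(E_neomarmorata,(E_marmorata,E_longa)))))))N2)N)L)J)H)F)D)B)Eidmanacris;
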