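# trait: habitat
# states: str str/cav cav
E_fusca	str
E_melloi	str
E_endophallica	str
E_minuta	str
E_bidentata	str
E_putuhra	str
E_tridentata	str
E_simoesi	str
E_eliethae	str
E_papaveroi	str
E_fontanettiae	str
E_larvaeformis	str/cav
E_septentrionalis	str/cav
E_speluncae	cav
E_multispinosa	str
E_dissimilis	str/cav
E_meridionalis	str/cav
E_alboannulata	str/cav
E_suassunai	str/cav
E_scopula	cav
E_desutterae	str/cav
E_corumbatai	str/cav
E_gigas	str/cav
E_caipira	str/cav
E_bernardii	str/cav
E_neomarmorata	cav
E_marmorata	str/cav
E_longa	str/cav
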