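# trait: size_class
# states: 0 1 2 3 4 5
E_fusca	3
E_melloi	1
E_endophallica	2
E_minuta	0
E_bidentata	1
E_putuhra	1
E_tridentata	1
E_simoesi	1
E_eliethae	2
E_papaveroi	2
E_fontanettiae	1
E_larvaeformis	4
E_septentrionalis	2
E_speluncae	3
E_multispinosa	3
E_dissimilis	2
E_meridionalis	2
E_alboannulata	3
E_suassunai	3
E_scopula	3
E_desutterae	3
E_corumbatai	3
E_gigas	3
E_caipira	5
E_bernardii	4
E_neomarmorata	3
E_marmorata	4
E_longa	4
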