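# trait: metanotal_bristles
# states: anterior entire
E_fusca	anterior
E_melloi	anterior
E_endophallica	anterior
E_minuta	anterior
E_bidentata	anterior
E_putuhra	anterior
E_tridentata	anterior
E_simoesi	anterior
E_eliethae	anterior
E_papaveroi	anterior
E_fontanettiae	anterior
E_larvaeformis	anterior
E_septentrionalis	anterior
E_speluncae	anterior
E_multispinosa	anterior
E_dissimilis	entire
E_meridionalis	entire
E_alboannulata	entire
E_suassunai	entire
E_scopula	entire
E_desutterae	entire
E_corumbatai	entire
E_gigas	entire
E_caipira	entire
E_bernardii	entire
E_neomarmorata	entire
E_marmorata	entire
E_longa	entire
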