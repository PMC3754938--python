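(P_turgiduloides,(P_fraudulenta,(P_multistriata,(P_multiseries,P_pungens)),(P_galaxiae,((P_pseudodelicatissima,P_cf_delicatissima_new,P_delicatissima),P_dolorosa,P_arenysensis))));
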