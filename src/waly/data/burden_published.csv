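# Published per-disease burden components (time trade-off weights, anchoring
# impediment "respiratory distress" excluded): mean years lived with impaired
# welfare (yliw) and mean years of life lost (yll), with 95% uncertainty
# interval bounds as reported.
disease,yliw,yliw_low,yliw_high,yll,yll_low,yll_high
mitral_valve_disease,0.81,0.14,1.70,3.11,1.10,7.08
dilated_cardiomyopathy,0.31,0.10,0.60,7.09,5.85,8.33
chronic_kidney_disease,0.58,0.29,0.84,3.52,1.10,8.76
diabetes_mellitus,1.00,0.90,1.17,3.62,1.13,7.34
atopic_dermatitis,9.73,7.17,11.8,0.00,0.00,0.00
splenic_haemangiosarcoma,0.49,0.46,0.52,4.36,2.59,6.23
appendicular_osteosarcoma,0.94,0.67,1.30,6.00,2.90,9.90
cranial_cruciate_ligament_disease,3.47,2.39,4.58,0.00,0.00,0.00
thoracolumbar_ivdd,2.51,1.37,3.51,0.32,0.16,0.45
cervical_spondylomyelopathy,2.23,1.67,3.17,4.26,2.28,6.63
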