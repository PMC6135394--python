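# Published impaired welfare weights for the 35 impediments, anchored by
# visual analogue scale (vas) and time trade-off (tto), both with the
# anchoring impediment "respiratory distress" excluded from model building.
impediment,method,variant,mean,ui_low,ui_high
heart_failure_mild_moderate,vas,minus_respiratory_distress,0.357,0.305,0.411
heart_failure_severe,vas,minus_respiratory_distress,0.646,0.524,0.755
cancer_diagnosis_therapy,vas,minus_respiratory_distress,0.728,0.599,0.833
cancer_lung_metastasis,vas,minus_respiratory_distress,0.757,0.679,0.824
msk_one_limb_mild,vas,minus_respiratory_distress,0.387,0.332,0.444
msk_one_limb_moderate,vas,minus_respiratory_distress,0.760,0.637,0.858
msk_one_limb_severe,vas,minus_respiratory_distress,0.786,0.675,0.872
vision_impairment_blindness,vas,minus_respiratory_distress,0.602,0.490,0.707
overweight,vas,minus_respiratory_distress,0.504,0.420,0.588
obesity,vas,minus_respiratory_distress,0.406,0.348,0.467
spinal_hyperesthesia_mild,vas,minus_respiratory_distress,0.777,0.661,0.868
spinal_hyperesthesia_more_severe,vas,minus_respiratory_distress,0.740,0.612,0.843
ataxia_paraparesis,vas,minus_respiratory_distress,0.504,0.420,0.587
nonambulatory_paraparesis,vas,minus_respiratory_distress,0.740,0.614,0.843
nonambulatory_paraparesis_wheelchair,vas,minus_respiratory_distress,0.641,0.520,0.750
nonambulatory_tetraparesis,vas,minus_respiratory_distress,0.795,0.698,0.872
urinary_incontinence_umn,vas,minus_respiratory_distress,0.747,0.621,0.848
urinary_incontinence_lmn,vas,minus_respiratory_distress,0.783,0.670,0.871
anaemia_mild,vas,minus_respiratory_distress,0.224,0.163,0.295
anaemia_moderate,vas,minus_respiratory_distress,0.693,0.565,0.803
anaemia_severe,vas,minus_respiratory_distress,0.795,0.696,0.872
pruritus_mild,vas,minus_respiratory_distress,0.560,0.459,0.657
pruritus_moderate,vas,minus_respiratory_distress,0.748,0.623,0.849
pruritus_severe,vas,minus_respiratory_distress,0.750,0.624,0.850
respiratory_distress,vas,minus_respiratory_distress,0.796,0.713,0.865
polyuria_polydipsia,vas,minus_respiratory_distress,0.332,0.282,0.386
vomiting_frequent,vas,minus_respiratory_distress,0.796,0.709,0.866
diarrhoea_frequent,vas,minus_respiratory_distress,0.502,0.418,0.586
abdominal_pain,vas,minus_respiratory_distress,0.741,0.613,0.844
lethargy_anorexia,vas,minus_respiratory_distress,0.736,0.609,0.840
fever,vas,minus_respiratory_distress,0.796,0.700,0.871
amputation_one_limb,vas,minus_respiratory_distress,0.134,0.072,0.223
frequent_vet_visits,vas,minus_respiratory_distress,0.244,0.185,0.310
sc_injections,vas,minus_respiratory_distress,0.555,0.455,0.652
death,vas,minus_respiratory_distress,0.562,0.460,0.659
heart_failure_mild_moderate,tto,minus_respiratory_distress,0.337,0.304,0.372
heart_failure_severe,tto,minus_respiratory_distress,0.655,0.575,0.728
cancer_diagnosis_therapy,tto,minus_respiratory_distress,0.752,0.673,0.821
cancer_lung_metastasis,tto,minus_respiratory_distress,0.857,0.823,0.887
msk_one_limb_mild,tto,minus_respiratory_distress,0.368,0.332,0.405
msk_one_limb_moderate,tto,minus_respiratory_distress,0.793,0.720,0.854
msk_one_limb_severe,tto,minus_respiratory_distress,0.829,0.767,0.879
vision_impairment_blindness,tto,minus_respiratory_distress,0.604,0.530,0.675
overweight,tto,minus_respiratory_distress,0.494,0.438,0.550
obesity,tto,minus_respiratory_distress,0.389,0.350,0.428
spinal_hyperesthesia_mild,tto,minus_respiratory_distress,0.815,0.749,0.870
spinal_hyperesthesia_more_severe,tto,minus_respiratory_distress,0.767,0.689,0.833
ataxia_paraparesis,tto,minus_respiratory_distress,0.494,0.437,0.549
nonambulatory_paraparesis,tto,minus_respiratory_distress,0.767,0.691,0.833
nonambulatory_paraparesis_wheelchair,tto,minus_respiratory_distress,0.649,0.570,0.722
nonambulatory_tetraparesis,tto,minus_respiratory_distress,0.846,0.795,0.888
urinary_incontinence_umn,tto,minus_respiratory_distress,0.776,0.700,0.840
urinary_incontinence_lmn,tto,minus_respiratory_distress,0.825,0.762,0.876
anaemia_mild,tto,minus_respiratory_distress,0.203,0.165,0.247
anaemia_moderate,tto,minus_respiratory_distress,0.711,0.629,0.783
anaemia_severe,tto,minus_respiratory_distress,0.845,0.793,0.888
pruritus_mild,tto,minus_respiratory_distress,0.556,0.489,0.621
pruritus_moderate,tto,minus_respiratory_distress,0.778,0.702,0.842
pruritus_severe,tto,minus_respiratory_distress,0.780,0.704,0.843
respiratory_distress,tto,minus_respiratory_distress,0.857,0.815,0.892
polyuria_polydipsia,tto,minus_respiratory_distress,0.312,0.279,0.347
vomiting_frequent,tto,minus_respiratory_distress,0.855,0.811,0.892
diarrhoea_frequent,tto,minus_respiratory_distress,0.492,0.436,0.548
abdominal_pain,tto,minus_respiratory_distress,0.768,0.691,0.835
lethargy_anorexia,tto,minus_respiratory_distress,0.763,0.685,0.830
fever,tto,minus_respiratory_distress,0.848,0.799,0.889
amputation_one_limb,tto,minus_respiratory_distress,0.117,0.078,0.168
frequent_vet_visits,tto,minus_respiratory_distress,0.223,0.186,0.264
sc_injections,tto,minus_respiratory_distress,0.551,0.484,0.616
death,tto,minus_respiratory_distress,0.558,0.491,0.624
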