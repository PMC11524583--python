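drug_id,fu_brain,ps_obs_ul_min_g,papp_mono_mean_1e6_cm_s,papp_mono_sem_1e6_cm_s,ps_pre_mono_printed_ul_min_g,papp_triple_mean_1e6_cm_s,papp_triple_sem_1e6_cm_s,ps_pre_triple_printed_ul_min_g
Amantadine,0.1985,116.10,6.84,0.95,310.22,3.64,0.26,165.23
Amitriptyline,0.01,4608.00,15.24,0.64,13716.00,14.61,0.27,13149.00
Bupropion,0.12,1519.20,15.19,0.20,1139.58,11.34,0.44,850.58
Carbamazepine,0.116,959.40,34.37,1.26,2666.89,11.71,0.15,908.69
Clozapine,0.014,2260.80,38.97,0.54,25052.57,12.87,2.06,8272.72
Donepezil,0.07,1581.30,20.91,0.75,2688.43,14.47,0.84,1860.43
Doxepin,0.025,2192.40,16.88,1.08,6076.80,10.66,0.92,3837.60
Fluoxetine,0.004,2698.20,11.48,0.85,25830.00,9.97,1.03,22430.25
Gabapentin,0.782,162.90,16.75,1.62,192.77,8.78,0.23,101.05
Lamotrigine,0.273,126.00,14.26,0.37,470.11,5.97,0.11,196.88
Metoclopramide,0.365,125.10,14.14,1.44,348.66,6.63,0.42,163.41
Midazolam,0.045,2727.00,25.30,1.00,5060.00,19.09,0.24,3818.00
Mirtazapine,0.08,1912.50,23.44,0.44,2637.00,17.86,0.21,2009.25
Olanzapine,0.034,2279.70,22.91,3.80,6064.41,12.49,0.53,3306.18
Prazosin,0.09,169.20,5.61,0.38,560.93,2.81,0.52,280.99
Risperidone,0.099,849.60,16.10,2.87,1463.64,11.70,0.25,1063.64
Venlafaxine,0.205,584.10,9.58,0.28,420.60,8.25,0.36,362.02
Verapamil,0.033,335.70,7.21,0.41,1965.24,5.56,0.06,1517.67
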