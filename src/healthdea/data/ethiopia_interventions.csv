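policy,govt_expenditure,household_expenditure_averted,deaths_averted,impoverishment_averted
Rotavirus vaccine,800,180,510,270
Pneumococcal vaccine,1200,110,1700,170
Measles vaccine,260,9,890,14
Diarrhoea treatment,50000,26000,3600,40000
Pneumonia treatment,31000,15000,4100,23000
Malaria treatment,670,300,410,460
Caesarean section,420,270,590,410
Tuberculosis treatment,6900,4400,2600,6700
Hypertension treatment,1300,730,140,1100
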