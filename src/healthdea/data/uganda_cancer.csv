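policy,cost,deaths_averted,impoverishment_averted,catastrophic_expense_averted,equity_score
Universal public finance,3320,3.0,0.7,4.2,-0.08
Task-shifting,301,3.2,-8.1,-34.8,-0.16
Universal public finance + task-shifting,3670,8.7,-1.8,-23.1,-0.24
Universal public finance + vouchers,24470,30.7,123.8,218.6,0.24
Task-shifting + vouchers,13701,18.7,18.0,57.1,-0.05
Universal public finance + task-shifting + vouchers,25009,33.6,127.2,218.6,0.23
Two-week mission trip,40438,1.5,2.4,7.2,0.23
Mobile surgical unit,7047,42.8,106.6,99.4,0.19
Cancer hospital,54431,30.3,74.9,81.2,0.13
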