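policy,cost,deaths_averted,catastrophic_expenditure_averted
Policy A,175000,200,-40
Policy B,150000,40,20
Policy C,200000,80,-60
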