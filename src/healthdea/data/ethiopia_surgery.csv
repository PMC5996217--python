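policy,cost,deaths_averted,impoverishment_averted
Universal public finance,945313,22.99,360.71
Universal public finance + vouchers,5516092,58.64,2646.68
Task-shifting,401491,252.55,-578.43
Universal public finance + task-shifting,2354435,289.12,-231.17
Universal public finance + task-shifting + vouchers,9705724,327.51,2646.68
Task-shifting + vouchers,3201492,278.06,-372.65
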