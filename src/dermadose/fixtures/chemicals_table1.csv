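name,MW,logKow,pKa,pKa_type,fu_plasma,Pvap_meas_25,Pvap_pred_25,Pvap_pred_32,solubility,density
BR,229.20,1.80,,,0.2,,8.3e-6,2.3e-5,8.2,0.93
CAP,305.20,3.20,9.93,acid,0.05,,1.3e-8,4.3e-8,0.06,1.04
DGMME,120.08,-1.16,,,0.9,2.5e-1,1.1e-1,2.1e-1,,1.02
DGMBE,162.13,0.44,,,0.8,2.2e-2,1.1e-2,2.2e-2,,0.95
DMF,73.05,-0.83,,,0.85,3.9,3.5,5.4,,0.944
2-EH,130.14,2.72,,,0.3,1.4e-1,1.9e-1,3.4e-1,0.88,0.833
MPA,132.08,0.48,,,0.7,,7.7,5.0,50,0.97
2-ME,76.05,-0.70,,,0.9,9.5,5.6,9.08,,0.965
TGA,91.99,0.14,3.67,acid,0.8,8.7e-2,4.2e-1,6.9e-1,,1.32
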