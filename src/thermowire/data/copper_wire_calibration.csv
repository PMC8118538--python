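fa_deg,b1rms_uT,energy_J,tmax_C
0,0.6,0,0.2
10,0.8,150,0.7
20,1.1,602,1.4
30,1.4,1354,2.6
40,1.9,2407,6.7
50,2.3,3761,9
60,2.8,5415,15.7
70,3.2,7371,24
80,3.8,9627,29
90,4.1,12185,32.4
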