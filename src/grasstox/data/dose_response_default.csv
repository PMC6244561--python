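herbicide,species,er50,er50_se,slope_b,slope_se
RoundUp,B. erectus,323.69,12.50,2.14,0.18
RoundUp,C. cristatus,94.88,5.88,2.07,0.31
RoundUp,G. mollugo,104.88,1.62,4.57,0.33
RoundUp,L. hispidus,111.16,4.47,2.24,0.22
RoundUp,S. nutans,149.93,12.09,1.46,0.18
RoundUp,T. pratense,233.51,2.33,1.36,0.11
Monitor,B. erectus,25.23,7.20,0.64,0.12
Monitor,C. cristatus,1.73,0.44,0.67,0.17
Monitor,G. mollugo,1.52,0.06,1.93,0.19
Monitor,L. hispidus,1.80,0.21,0.86,0.11
Monitor,S. nutans,1.68,0.21,0.69,0.08
Monitor,T. pratense,4.74,,-0.08,
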