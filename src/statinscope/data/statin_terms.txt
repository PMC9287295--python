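# Statin term dictionary: one lowercase term per line.
# Lines starting with '!' are trap exclusions: tokens that contain a term as a
# substring but are not statins.
statin
atorvastatin
simvastatin
rosuvastatin
pravastatin
lovastatin
fluvastatin
pitavastatin
cerivastatin
lipitor
crestor
zocor
pravachol
mevacor
lescol
livalo
!nystatin
!sandostatin
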