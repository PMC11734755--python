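[target]
gdsl
lipase
esterase
[nontarget]
acyltransferase
glycosyltransferase
methyltransferase
aminotransferase
cytochrome p450
peroxidase
dioxygenase
decarboxylase
ligase
synthase
polyketide
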