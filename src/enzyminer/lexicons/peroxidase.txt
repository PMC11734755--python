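[target]
peroxidase
prx
[nontarget]
acyltransferase
glycosyltransferase
methyltransferase
aminotransferase
cytochrome p450
dioxygenase
decarboxylase
ligase
synthase
lipase
polyketide
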