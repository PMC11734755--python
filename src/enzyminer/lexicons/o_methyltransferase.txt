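[target]
methyltransferase
omt
[nontarget]
acyltransferase
glycosyltransferase
aminotransferase
cytochrome p450
peroxidase
dioxygenase
hydroxylase
decarboxylase
ligase
synthase
lipase
polyketide
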