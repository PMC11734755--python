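[target]
aminotransferase
transaminase
[nontarget]
acyltransferase
glycosyltransferase
methyltransferase
cytochrome p450
peroxidase
dioxygenase
decarboxylase
ligase
synthase
lipase
polyketide
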