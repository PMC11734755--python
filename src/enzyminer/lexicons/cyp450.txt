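[target]
cytochrome p450
cyp
monooxygenase
[nontarget]
acyltransferase
glycosyltransferase
methyltransferase
aminotransferase
peroxidase
decarboxylase
ligase
lipase
polyketide
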