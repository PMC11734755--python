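# Name patterns for recognizing BAHD acyltransferase entries and common
# nontarget-family contaminants. Case-insensitive substring match.
[target]
bahd
acyltransferase
acyl transferase
hydroxycinnamoyl
[nontarget]
glycosyltransferase
glucosyltransferase
methyltransferase
aminotransferase
cytochrome p450
peroxidase
dioxygenase
oxygenase
hydroxylase
decarboxylase
carboxylase
ligase
synthase
lipase
polyketide
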