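Based on the title and abstract, is this a paper that directly tests the
in vitro biochemical activity of an enzyme from the family "{family}"?
Respond 1 for yes or 0 for no.
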