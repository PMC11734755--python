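Based on the title and abstract, does this paper likely describe a
characterized biochemical activity of an enzyme belonging to the family
"{family}"? Respond 1 for yes or 0 for no.
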