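From the manuscript below, extract every experimentally characterized
enzyme activity of the stated enzyme family. Report each activity as an
object with the fields: enzyme_name, enzyme_abbrev, species, sequence_ids
(GenBank or UniProt identifiers), acceptors, donors, products, notes.
Preserve compound names verbatim as written in the paper. Return a JSON
object {"activities": [...]}; return {"activities": []} if the paper
reports no activity of this family.
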