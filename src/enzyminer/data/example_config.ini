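# Complete commented example configuration.
# Lists are comma-separated; year ranges are inclusive.

[search]
family = BAHD acyltransferase
journals = Plant Cell, Plant Journal, Phytochemistry
keywords = acyltransferase, enzyme assay, kinetic, substrate
exclude_reviews = true
use_elink = false
years = 1990-2024
per_query_limit = 10000

[screen]
template = q11
temperature = 0.5
seed = 1

[extract]
mode = merge
pdf_dir = run/pdfs

[curate]
lexicon = bahd_acyltransferase
lineage = run/lineage.tsv
idmap = run/idmap.tsv

[grade]
hqd = run/hqd.tsv
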