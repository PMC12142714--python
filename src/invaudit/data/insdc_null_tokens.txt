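# INSDC / BioSample null placeholders, one per line, matched case-insensitively
# after surrounding-whitespace strip. An attribute whose value is any of these
# is treated exactly like an absent attribute.
missing
not collected
not applicable
not provided
restricted access
unknown
unspecified
na
n/a
none
not determined
nd
-
missing: control sample
missing: sample group
missing: synthetic construct
missing: lab stock
missing: third party data
missing: data agreement established pre-2023
missing: endangered species
missing: human-identifiable
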