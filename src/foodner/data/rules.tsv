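# Default semantic-tag correction rules: trigger<TAB>ACTION<TAB>TAG[<TAB>REPLACEMENT]
# Fired when the trigger token occurs (case-insensitively) inside a food chunk.
mixture	REMOVE_TAG	AG.01.af[Tea manufacture]
mashed	REMOVE_TAG	AG.01.ae.03[Brewing]
water	REPLACE_TAG	AG.01[Food]	AG.01.z[Water]
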