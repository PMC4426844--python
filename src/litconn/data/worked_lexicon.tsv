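region_id	preferred_name	synonyms	parent_id	source
WE:ROOT	basal ganglia and midbrain			worked
WE:AC	nucleus accumbens	accumbens nucleus	WE:ROOT	worked
WE:SN	substantia nigra		WE:ROOT	worked
WE:VTA	ventral tegmental area		WE:ROOT	worked
WE:DR	dorsal raphe nucleus		WE:ROOT	worked
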