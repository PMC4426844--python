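{"id": "worked-1", "source_class": "abstract", "text": "The nucleus accumbens (AC) receives projections from both the substantia nigra (SN) and the ventral tegmental area (VTA) (Dworkin, 1988).", "metadata": {"expected_pairs": [["WE:AC", "WE:SN"], ["WE:AC", "WE:VTA"]]}}
{"id": "worked-2", "source_class": "abstract", "text": "Substantial numbers of tyrosine hydroxylase-immunoreactive cells in the dorsal raphe nucleus (DR) were found to project to the nucleus accumbens (AC) (Stratford and Wirtshafter, 1990).", "metadata": {"expected_pairs": [["WE:DR", "WE:AC"]]}}
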