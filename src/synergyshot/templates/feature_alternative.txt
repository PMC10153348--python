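Determine cancer drug combination synergy for the following drugs. Allowed synergies: Positive, Not positive. drug1: {drug1}; drug2: {drug2}; cell line: {cell_line}; tissue: {tissue}; sensitivity1: {sensitivity1}; sensitivity2: {sensitivity2}
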