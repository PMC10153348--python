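The first drug is {drug1}. The second drug is {drug2}. The cell line is {cell_line}. Tissue is {tissue}. The first drug's sensitivity using relative inhibition is {sensitivity1}. The second drug's sensitivity using relative inhibition is {sensitivity2}.
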