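# Controlled vocabulary of experimental evidence codes (one per line, editable).
in-vitro assay
in-vivo assay
heterologous expression
knock-out
site-directed mutagenesis
sequence-based prediction
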