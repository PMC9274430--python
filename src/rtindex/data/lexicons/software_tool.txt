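# Software projects and tools
GraphPad Prism
ImageJ
FlowJo
SPSS
MATLAB
Fiji software
Seurat
Bowtie2
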