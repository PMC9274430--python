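{
  "comment": "Bundled name-to-RRID suggestion catalog. Keys are resource names as they appear in text; lookups are done on a normalized form (casefold, punctuation stripped). A resource mention whose name appears here is treated as uniquely identifiable even without an inline RRID.",
  "entries": {
    "ImageJ": "SCR_003070",
    "Fiji software": "SCR_002285",
    "GraphPad Prism": "SCR_002798",
    "FlowJo": "SCR_008520",
    "Seurat": "SCR_016341",
    "Bowtie2": "SCR_016368",
    "HeLa cells": "CVCL_0030",
    "HEK293 cells": "CVCL_0045",
    "HEK293T cells": "CVCL_0063",
    "MCF-7 cells": "CVCL_0031",
    "Jurkat cells": "CVCL_0065",
    "C57BL/6J mice": "IMSR_JAX:000664",
    "BALB/c mice": "IMSR_JAX:000651",
    "Drosophila melanogaster": "NCBITaxon_7227",
    "psPAX2": "Addgene_12260",
    "pMD2.G": "Addgene_12259",
    "pLKO.1": "Addgene_10878",
    "pEGFP-N1": "Addgene_6085"
  }
}
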