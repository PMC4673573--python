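5d8004a6ac47738e4c1515d96d496b984499d05deda1a3779ce75319d34df568  spectra/cellopentaose_synthetic.tsv
d64c3b9ecc71dba61dc941e7bfa020e022096062d9f26c1a262b295fe79397cb  spectra/laminaripentaose_synthetic.tsv
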