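region
lh.bankssts
lh.caudalanteriorcingulate
lh.caudalmiddlefrontal
lh.cuneus
lh.entorhinal
lh.frontalpole
lh.fusiform
lh.inferiorparietal
lh.inferiortemporal
lh.insula
lh.isthmuscingulate
lh.lateraloccipital
lh.lateralorbitofrontal
lh.lingual
lh.medialorbitofrontal
lh.middletemporal
lh.paracentral
lh.parahippocampal
lh.parsopercularis
lh.parsorbitalis
lh.parstriangularis
lh.pericalcarine
lh.postcentral
lh.posteriorcingulate
lh.precentral
lh.precuneus
lh.rostralanteriorcingulate
lh.rostralmiddlefrontal
lh.superiorfrontal
lh.superiorparietal
lh.superiortemporal
lh.supramarginal
lh.temporalpole
lh.transversetemporal
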