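raw_label	category
Vesicles	Vesicles
Plasma membrane	Plasma membrane
Nucleus	Nucleus
Mitochondria	Mitochondria
Lysosomes	Lysosomes
Golgi apparatus	Golgi apparatus
Endoplasmic reticulum	Endoplasmic reticulum
Cytosol	Cytosol
Cell adhesion	Cell adhesion
Cytoskeleton	Cytoskeleton
Cytoplasmic bodies	Cytoplasmic bodies
Nuclear membrane	Nucleus
Nucleoplasm	Nucleus
Nucleoli	Nucleus
Nuclear speckles	Nucleus
Nuclear bodies	Nucleus
Nucleoli rim	Nucleus
Mitotic chromosome	Nucleus
Kinetochore	Nucleus
Microtubules	Cytoskeleton
Actin filaments	Cytoskeleton
Intermediate filaments	Cytoskeleton
Microtubule ends	Cytoskeleton
Midbody	Cell division
Midbody ring	Cell division
Cleavage furrow	Cell division
Mitotic spindle	Cell division
Cytokinetic bridge	Cell division
Centrosome	Centrosome cilium
Primary cilium	Centrosome cilium
Basal body	Centrosome cilium
Flagellar centriole	Centrosome cilium
Primary cilium transition zone	Centrosome cilium
Primary cilium tip	Centrosome cilium
Centriolar satellite	Centrosome cilium
Cell Junctions	Cell adhesion
Focal adhesion sites	Cell adhesion
Aggresome	Cytoplasmic bodies
Rods & Rings	Cytoplasmic bodies
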