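# prefix	iri	label	source
iao	http://purl.obolibrary.org/obo/IAO_0000310	document	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000315	abstract	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000324	author list	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000316	introduction	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000317	methods section	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000318	results section	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000319	discussion section	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000615	conclusion section	Information Artifact Ontology
iao	http://purl.obolibrary.org/obo/IAO_0000320	references section	Information Artifact Ontology
obi	http://purl.obolibrary.org/obo/OBI_0000070	assay	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0002119	microscopy assay	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0000659	specimen collection process	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0000094	material processing	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0100051	specimen	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0000968	device	Ontology for Biomedical Investigations
obi	http://purl.obolibrary.org/obo/OBI_0000272	protocol	Ontology for Biomedical Investigations
bfo	http://purl.obolibrary.org/obo/BFO_0000029	site	Basic Formal Ontology
bfo	http://purl.obolibrary.org/obo/BFO_0000040	material entity	Basic Formal Ontology
pato	http://purl.obolibrary.org/obo/PATO_0000001	quality	Phenotype and Trait Ontology
pato	http://purl.obolibrary.org/obo/PATO_0000150	texture	Phenotype and Trait Ontology
pato	http://purl.obolibrary.org/obo/PATO_0001359	rugose	Phenotype and Trait Ontology
pato	http://purl.obolibrary.org/obo/PATO_0000701	smooth	Phenotype and Trait Ontology
pato	http://purl.obolibrary.org/obo/PATO_0000918	volume	Phenotype and Trait Ontology
pato	http://purl.obolibrary.org/obo/PATO_0000122	length	Phenotype and Trait Ontology
uo	http://purl.obolibrary.org/obo/UO_0000098	milliliter	Units Ontology
uo	http://purl.obolibrary.org/obo/UO_0000008	meter	Units Ontology
uo	http://purl.obolibrary.org/obo/UO_0000015	centimeter	Units Ontology
uo	http://purl.obolibrary.org/obo/UO_0000016	millimeter	Units Ontology
uo	http://purl.obolibrary.org/obo/UO_0000017	micrometer	Units Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000090	adult	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000397	head	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0001074	thorax	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000101	antenna	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000494	leg	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0001089	wing	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000506	mandible	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000576	mesosoma	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000626	metasoma	Hymenoptera Anatomy Ontology
hao	http://purl.obolibrary.org/obo/HAO_0000181	compound eye	Hymenoptera Anatomy Ontology
ncbitaxon	http://purl.obolibrary.org/obo/NCBITaxon_9606	Homo sapiens	NCBI organismal classification
ngo	https://example.org/anatomy-kg/ngo/InstanceAnatomy	instance anatomy	local named-graph ontology
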