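code,scientific_name,family,growth_form
ABCO,Abies concolor,Pinaceae,tree
ABMA,Abies magnifica,Pinaceae,tree
ABPR,Abies procera,Pinaceae,tree
PILA,Pinus lambertiana,Pinaceae,tree
PIPO,Pinus ponderosa,Pinaceae,tree
PSME,Pseudotsuga menziesii,Pinaceae,tree
CADE,Calocedrus decurrens,Cupressaceae,tree
CONU,Cornus nuttallii,Cornaceae,tree
QUKE,Quercus kelloggii,Fagaceae,tree
PRSP,Prunus spp.,Rosaceae,tree
SASC,Salix scouleriana,Salicaceae,tree
RHCA,Rhamnus californica,Rhamnaceae,tree
UNKN,Unknown,Unknown,tree
ARPA,Arctostaphylos patula,Ericaceae,shrub
CECO,Ceanothus cordulatus,Rhamnaceae,shrub
CEIN,Ceanothus integerrimus,Rhamnaceae,shrub
CEPA,Ceanothus parvifolius,Rhamnaceae,shrub
CHSE,Chrysolepis sempervirens,Fagaceae,shrub
COCO,Corylus cornuta var. californica,Betulaceae,shrub
COSE,Cornus sericea,Cornaceae,shrub
LEDA,Leucothoe davisiae,Ericaceae,shrub
VAUL,Vaccinium uliginosum,Ericaceae,shrub
SARA,Sambucus racemosa,Adoxaceae,shrub
RHOC,Rhododendron occidentale,Ericaceae,shrub
RINE,Ribes nevadense,Grossulariaceae,shrub
RIRO,Ribes roezlii,Grossulariaceae,shrub
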