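brand,ingredient
revlimid,lenalidomide
velcade,bortezomib
darzalex,daratumumab
darzalex faspro,daratumumab
kyprolis,carfilzomib
pomalyst,pomalidomide
ninlaro,ixazomib
empliciti,elotuzumab
sarclisa,isatuximab
xpovio,selinexor
blenrep,belantamab mafodotin
thalomid,thalidomide
decadron,dexamethasone
alkeran,melphalan
cytoxan,cyclophosphamide
adriamycin,doxorubicin
doxil,doxorubicin
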