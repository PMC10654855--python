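term,concept_id,preferred_name
kanker,C0001,maligniteit
maligniteit,C0001,maligniteit
tumor,C0002,tumor
longcarcinoom,C0003,longcarcinoom
metastase,C0004,metastase
gemetastaseerd,C0004,metastase
pneumonie,C0005,pneumonie
longontsteking,C0005,pneumonie
hoest,C0006,hoest
koorts,C0007,koorts
astma,C0008,astma
copd,C0009,copd
hartfalen,C0010,hartfalen
decompensatio cordis,C0010,hartfalen
diabetes mellitus,C0011,diabetes mellitus
diabetes,C0012,diabetes
hypertensie,C0013,hypertensie
benauwd,C0014,dyspnoe
benauwdheid,C0014,dyspnoe
dyspnoe,C0014,dyspnoe
pijn op de borst,C0015,thoracale pijn
depressie,C0016,depressie
eczeem,C0017,eczeem
prednison,C0018,prednison
prednisolon,C0019,prednisolon
angina pectoris,C0020,angina pectoris
boezemfibrilleren,C0021,atriumfibrilleren
atriumfibrilleren,C0021,atriumfibrilleren
dementie,C0022,dementie
beroerte,C0023,cva
cva,C0023,cva
migraine,C0024,migraine
obstipatie,C0025,obstipatie
diarree,C0026,diarree
duizeligheid,C0027,duizeligheid
moeheid,C0028,vermoeidheid
vermoeidheid,C0028,vermoeidheid
anemie,C0029,anemie
fractuur,C0030,fractuur
artrose,C0031,artrose
reuma,C0032,reuma
nierfalen,C0033,nierfalen
palliatieve zorg,C0034,palliatieve zorg
palliatief,C0034,palliatieve zorg
exacerbatie,C0035,exacerbatie
infectie,C0036,infectie
griep,C0037,influenza
influenza,C0037,influenza
allergie,C0038,allergie
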