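trigger,category,direction,terminator
geen,negated,forward,0
niet,negated,forward,0
geen aanwijzing voor,negated,forward,0
geen aanwijzingen voor,negated,forward,0
geen tekenen van,negated,forward,0
zonder,negated,forward,0
negatief voor,negated,forward,0
vrij van,negated,forward,0
ontkent,negated,forward,0
uitgesloten,negated,backward,0
afwezig,negated,backward,0
niet aangetoond,negated,backward,0
niet waarschijnlijk,negated,backward,0
indien,hypothetical,forward,0
als,hypothetical,forward,0
mogelijk,hypothetical,forward,0
eventueel,hypothetical,forward,0
risico op,hypothetical,forward,0
verdenking op,hypothetical,forward,0
cave,hypothetical,forward,0
dd,hypothetical,forward,0
bij twijfel over,hypothetical,forward,0
voorgeschiedenis van,historical,forward,0
in het verleden,historical,bidirectional,0
destijds,historical,bidirectional,0
eerder,historical,forward,0
doorgemaakte,historical,forward,0
status na,historical,forward,0
bekend met,historical,forward,0
jaren geleden,historical,backward,0
moeder,experiencer_other,forward,0
vader,experiencer_other,forward,0
broer,experiencer_other,forward,0
zus,experiencer_other,forward,0
familie,experiencer_other,forward,0
partner,experiencer_other,forward,0
echtgenoot,experiencer_other,forward,0
in de familie,experiencer_other,backward,0
maar,,bidirectional,1
echter,,bidirectional,1
behalve,,bidirectional,1
hoewel,,bidirectional,1
toch,,bidirectional,1
desondanks,,bidirectional,1
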