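# Continental-Spain province contiguity (47 areas), reconstructed from
# public first-order contiguity: two provinces are neighbours if they share
# a land border.  Synthetic-study topology fixture; ASCII province slugs.
a_coruna lugo
a_coruna pontevedra
lugo pontevedra
lugo ourense
lugo asturias
lugo leon
ourense pontevedra
ourense zamora
ourense leon
asturias leon
asturias cantabria
cantabria leon
cantabria palencia
cantabria burgos
cantabria vizcaya
vizcaya burgos
vizcaya alava
vizcaya guipuzcoa
guipuzcoa alava
guipuzcoa navarra
alava navarra
alava la_rioja
alava burgos
navarra la_rioja
navarra zaragoza
navarra huesca
la_rioja zaragoza
la_rioja soria
la_rioja burgos
burgos soria
burgos segovia
burgos valladolid
burgos palencia
palencia valladolid
palencia leon
leon zamora
leon valladolid
zamora valladolid
zamora salamanca
valladolid segovia
valladolid avila
valladolid salamanca
salamanca avila
salamanca caceres
avila segovia
avila madrid
avila toledo
avila caceres
segovia soria
segovia guadalajara
segovia madrid
soria zaragoza
soria guadalajara
zaragoza guadalajara
zaragoza teruel
zaragoza huesca
zaragoza lleida
zaragoza tarragona
huesca lleida
teruel guadalajara
teruel cuenca
teruel valencia
teruel castellon
teruel tarragona
lleida tarragona
lleida barcelona
lleida girona
girona barcelona
barcelona tarragona
tarragona castellon
castellon valencia
valencia cuenca
valencia albacete
valencia alicante
alicante albacete
alicante murcia
murcia albacete
murcia granada
murcia almeria
albacete cuenca
albacete granada
albacete jaen
albacete ciudad_real
cuenca guadalajara
cuenca ciudad_real
cuenca toledo
cuenca madrid
guadalajara madrid
madrid toledo
toledo ciudad_real
toledo badajoz
toledo caceres
ciudad_real jaen
ciudad_real cordoba
ciudad_real badajoz
jaen granada
jaen cordoba
granada almeria
granada malaga
granada cordoba
malaga cordoba
malaga sevilla
malaga cadiz
cadiz sevilla
sevilla cordoba
sevilla badajoz
sevilla huelva
cordoba badajoz
huelva badajoz
badajoz caceres
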