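# ENDS keyword table: columns language<TAB>term.
# The English list is canonical (singulars and plurals expanded).
# Non-English entries are illustrative placeholders, not authoritative
# translations; "xx" is a synthetic pseudo-language used by the test corpus.
language	term
en	electronic cigarette
en	electronic cigarettes
en	e cig
en	e cigs
en	e-cig
en	e-cigs
en	ecig
en	ecigs
en	e cigarette
en	e cigarettes
en	e-cigarette
en	e-cigarettes
en	ecigarette
en	ecigarettes
en	vape
en	vapes
en	vaper
en	vapers
en	vaping
es	cigarrillo electronico
es	cigarrillos electronicos
es	vapear
es	vapeo
pt	cigarro eletronico
pt	cigarros eletronicos
xx	zvapium
xx	zvapiums
xx	zcigeon
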