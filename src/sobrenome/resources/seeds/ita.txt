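# Stylized seed list: well-known surnames of Italian origin, used ONLY to
# parameterize the synthetic Markov name generator.
ROSSI
RUSSO
FERRARI
ESPOSITO
BIANCHI
ROMANO
COLOMBO
RICCI
MARINO
GRECO
BRUNO
GALLO
CONTI
DELUCA
MANCINI
GIORDANO
RIZZO
LOMBARDI
MORETTI
BARBIERI
FONTANA
SANTORO
MARIANI
RINALDI
CARUSO
FERRARA
GATTI
PELLEGRINI
PALUMBO
SARTORI
ZANELLA
BERTOLINI
VITALE
MARTINELLI
BELLINI
PAGANO
FARINA
GRASSI
TESTA
SERRA
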