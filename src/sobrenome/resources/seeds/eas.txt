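# Stylized seed list: well-known surnames of East European origin, used
# ONLY to parameterize the synthetic Markov name generator.
KOWALSKI
NOWAK
WISNIEWSKI
WOJCIK
KOWALCZYK
KAMINSKI
LEWANDOWSKI
ZIELINSKI
SZYMANSKI
WOZNIAK
DABROWSKI
KOZLOWSKI
JANKOWSKI
MAZUR
KWIATKOWSKI
KRAWCZYK
PIOTROWSKI
GRABOWSKI
NOWAKOWSKI
PAWLOWSKI
MICHALSKI
ADAMCZYK
DUDEK
ZAJAC
WIECZOREK
JABLONSKI
KROL
WROBEL
NOWICKI
MAJEWSKI
OLSZEWSKI
STEPIEN
MALINOWSKI
JAWORSKI
WITKOWSKI
WALCZAK
SIKORA
BARAN
RUTKOWSKI
SZEWCZYK
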