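# Common Brazilian given names (normalized form), used by split_name to
# consume (possibly compound) first names.  Swappable via configuration.
JOAO
MARIA
JOSE
ANA
ANTONIO
FRANCISCO
CARLOS
PAULO
PEDRO
LUCAS
LUIZ
LUIS
MARCOS
GABRIEL
RAFAEL
DANIEL
MARCELO
BRUNO
EDUARDO
FELIPE
RODRIGO
MANOEL
MANUEL
MATEUS
MATHEUS
ANDRE
FERNANDO
FABIO
LEONARDO
GUSTAVO
GUILHERME
LEANDRO
TIAGO
THIAGO
JULIANA
MARCIA
FERNANDA
PATRICIA
ALINE
SANDRA
CAMILA
AMANDA
BRUNA
JESSICA
LETICIA
VANESSA
MARIANA
GABRIELA
VERA
VITORIA
LAURA
BEATRIZ
LARISSA
CLAUDIA
ADRIANA
RENATA
SIMONE
ROSA
FRANCISCA
ANTONIA
CRISTIANE
DEBORA
CAROLINA
PAULA
HELENA
RAIMUNDO
SEBASTIAO
JORGE
ROBERTO
RICARDO
ALEXANDRE
VINICIUS
DIEGO
JOAQUIM
BENEDITO
RITA
SONIA
TEREZA
TERESA
REGINA
CELIA
MARLENE
IVONE
NEUSA
APARECIDA
FATIMA
LUCIA
MARINA
ISABEL
ELIANA
SUELI
VALERIA
TANIA
ROSANGELA
SOLANGE
ELAINE
KELLY
PRISCILA
TATIANE
DANIELA
MICHELE
SABRINA
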