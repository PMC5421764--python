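# Stylized seed list: well-known surnames of Iberian (Portuguese/Spanish)
# origin, used ONLY to parameterize the synthetic Markov name generator.
# Not a claim about any real population.
SILVA
SANTOS
OLIVEIRA
SOUZA
PEREIRA
COSTA
RODRIGUES
ALMEIDA
NASCIMENTO
LIMA
ARAUJO
FERNANDES
CARVALHO
GOMES
MARTINS
ROCHA
RIBEIRO
ALVES
MONTEIRO
MENDES
BARROS
FREITAS
BARBOSA
PINTO
MOREIRA
CAVALCANTI
DIAS
CASTRO
CAMPOS
CARDOSO
GONCALVES
LOPES
GARCIA
FERREIRA
TEIXEIRA
MORAES
AZEVEDO
VIEIRA
RAMOS
NUNES
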