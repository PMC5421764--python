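# Stylized seed list: well-known surnames of Japanese origin (romanized),
# used ONLY to parameterize the synthetic Markov name generator.
SATO
SUZUKI
TAKAHASHI
TANAKA
WATANABE
ITO
YAMAMOTO
NAKAMURA
KOBAYASHI
KATO
YOSHIDA
YAMADA
SASAKI
YAMAGUCHI
MATSUMOTO
INOUE
KIMURA
HAYASHI
SHIMIZU
SAITO
NAKAJIMA
MORI
IKEDA
HASHIMOTO
ABE
ISHIKAWA
OGAWA
GOTO
OKADA
HASEGAWA
FUJITA
MURAKAMI
KONDO
ISHII
SAKAMOTO
ENDO
AOKI
FUJII
NISHIMURA
FUKUDA
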