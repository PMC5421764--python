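# Stylized seed list: well-known surnames of German origin, used ONLY to
# parameterize the synthetic Markov name generator.
MULLER
SCHMIDT
SCHNEIDER
FISCHER
WEBER
MEYER
WAGNER
BECKER
SCHULZ
HOFFMANN
SCHAFER
KOCH
BAUER
RICHTER
KLEIN
WOLF
SCHRODER
NEUMANN
SCHWARZ
ZIMMERMANN
BRAUN
KRUGER
HOFMANN
HARTMANN
LANGE
SCHMITT
WERNER
KRAUSE
LEHMANN
KOHLER
FRANK
HERRMANN
KONIG
WALTER
HUBER
KAISER
FUCHS
PETERS
SCHUSTER
VOGEL
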