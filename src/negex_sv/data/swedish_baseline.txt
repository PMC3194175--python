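# Swedish trigger lexicon, baseline profile.
# Pre-negation (PREN) phrases are the published frequency / manual-annotation
# tables of the Swedish NegEx evaluation; English glosses in trailing comments.
# The published POST/PSEU/CONJ phrases are not printed in Swedish anywhere, so
# those sections are Swedish renderings of the English examples the algorithm
# description gives ("unlikely", "not certain if", conjunction scope cut).
#
# Dialect: <phrase> TAB+ [TAG], TAG in {PREN, POST, PSEU, CONJ}; '#' comments.

# --- pre-negation -----------------------------------------------------------
aldrig		[PREN]	# never
avsaknad av		[PREN]	# absence of
ej		[PREN]	# not
förnekar		[PREN]	# denies
har inte		[PREN]	# have not
icke		[PREN]	# non-, not
inga		[PREN]	# no (plural)
inga tecken		[PREN]	# no signs of
ingen		[PREN]	# no (common gender)
ingenting		[PREN]	# nothing
inget		[PREN]	# no (neuter gender)
inte		[PREN]	# not
inte har		[PREN]	# not have (inverted word order)
inte visar		[PREN]	# does not show (inverted word order)
intet		[PREN]	# nothing
utan		[PREN]	# without
utan tecken		[PREN]	# without signs of

# --- post-negation ----------------------------------------------------------
osannolik		[POST]	# unlikely (common gender)
osannolikt		[POST]	# unlikely (neuter gender)
osannolika		[POST]	# unlikely (plural)

# --- pseudo-negation --------------------------------------------------------
inte säkert om		[PSEU]	# not certain if
inte säker på		[PSEU]	# not sure of
utan tvekan		[PSEU]	# without doubt

# --- scope-terminating conjunctions -----------------------------------------
men		[CONJ]	# but
dock		[CONJ]	# however
fastän		[CONJ]	# although
förutom		[CONJ]	# apart from
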