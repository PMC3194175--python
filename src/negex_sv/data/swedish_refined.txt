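# Swedish trigger lexicon, refined profile.
# Identical to the baseline profile except that the trigger "icke" is removed:
# in clinical Swedish "icke" almost always opens a disease name ("icke
# allergisk astma"), so as a trigger it only produced false positives.
# The "utan" disambiguation rule (mask "utan" when an earlier "inte" occurs in
# the sentence) is an engine option tied to this profile, not a lexicon entry.

# --- pre-negation -----------------------------------------------------------
aldrig		[PREN]	# never
avsaknad av		[PREN]	# absence of
ej		[PREN]	# not
förnekar		[PREN]	# denies
har inte		[PREN]	# have not
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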