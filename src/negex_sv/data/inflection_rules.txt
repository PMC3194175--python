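# Default suffix-rule inflection paradigms for trigger-lexicon expansion.
#
# Format: section headers [adjective] / [verb] / [quantifier]; then one rule
# per line, `suffix-pattern TAB replacement1,replacement2,...`. An empty
# suffix-pattern is the catch-all rule and must terminate each section.
# Replacements substitute the matched suffix. Lines starting with '=' define
# an irregular override group: a comma-separated set of forms that expand to
# the whole group (first form is the lemma).

[adjective]
# doubled final consonant collapses before the neuter -t (sann -> sant)
nn	nn,nt,nna
mm	mm,mt,mma
# lemmas already ending in -t take only the plural/definite -a
t	t,ta
	t,a

[verb]
# first conjugation: -a -> -ar / -ade / -at
a	a,ar,ade,at

=ha,har,hade,haft
=se,ser,såg,sett
=kunna,kan,kunde,kunnat
=vara,är,var,varit
=förneka,förnekar,förnekade,förnekat

[quantifier]

=ingen,inga,inget
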