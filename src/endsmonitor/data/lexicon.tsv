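# Sentiment lexicon: columns token<TAB>weight (in [-1, 1]).
# Balanced default list; edit or replace to change scoring behavior.
token	weight
good	1
great	1
excellent	1
positive	1
beneficial	1
promising	1
encouraging	1
hopeful	1
successful	1
success	1
improve	1
improved	1
improvement	1
helpful	1
innovative	1
praised	1
celebrated	1
welcomed	1
thriving	1
breakthrough	1
effective	1
safe	1
safer	1
reassuring	1
optimistic	1
popular	1
win	1
winning	1
gain	1
benefit	1
bad	-1
poor	-1
negative	-1
harmful	-1
harm	-1
harms	-1
dangerous	-1
danger	-1
deadly	-1
toxic	-1
poisoning	-1
poison	-1
risky	-1
risk	-1
risks	-1
alarming	-1
worrying	-1
worse	-1
worst	-1
crisis	-1
epidemic	-1
death	-1
deaths	-1
disease	-1
illness	-1
injury	-1
injuries	-1
fear	-1
fears	-1
threat	-1
failure	-1
failed	-1
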