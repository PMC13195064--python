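word	language	form	ipa	note
den	czech	den	dɛn	plain Czech reading
din	hindi	din	dɪn	loanword reading: no palatalisation of d before i; short i is lax
djena	latvian	djena	djɛna	transliteration read letter-by-letter; j is a separate glide segment
hi	japanese	hi	ɦɪ	Czech reading of the transliteration: voiced glottal fricative, lax i
smer	czech	směr	smjɛr	me with hacek e read as [mj] (spelling pronunciation)
hoko	japanese	hókó	ɦoːkoː	macron/acute vowels of the romanisation read long
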