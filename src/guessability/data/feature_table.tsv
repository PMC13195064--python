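segment	syl	son	cons	cont	delrel	lat	nas	strid	voi	sg	cg	ant	cor	distr	lab	hi	lo	back	round	tense	long
p	-	-	+	-	-	-	-	-	-	-	-	+	-	0	+	-	-	-	-	0	-
b	-	-	+	-	-	-	-	-	+	-	-	+	-	0	+	-	-	-	-	0	-
t	-	-	+	-	-	-	-	-	-	-	-	+	+	-	-	-	-	-	-	0	-
d	-	-	+	-	-	-	-	-	+	-	-	+	+	-	-	-	-	-	-	0	-
c	-	-	+	-	-	-	-	-	-	-	-	-	+	+	-	+	-	-	-	0	-
ɟ	-	-	+	-	-	-	-	-	+	-	-	-	+	+	-	+	-	-	-	0	-
k	-	-	+	-	-	-	-	-	-	-	-	-	-	0	-	+	-	+	-	0	-
ɡ	-	-	+	-	-	-	-	-	+	-	-	-	-	0	-	+	-	+	-	0	-
ts	-	-	+	-	+	-	-	+	-	-	-	+	+	-	-	-	-	-	-	0	-
dʒ	-	-	+	-	+	-	-	+	+	-	-	-	+	+	-	-	-	-	-	0	-
tʃ	-	-	+	-	+	-	-	+	-	-	-	-	+	+	-	-	-	-	-	0	-
f	-	-	+	+	-	-	-	+	-	-	-	+	-	0	+	-	-	-	-	0	-
v	-	-	+	+	-	-	-	+	+	-	-	+	-	0	+	-	-	-	-	0	-
s	-	-	+	+	-	-	-	+	-	-	-	+	+	-	-	-	-	-	-	0	-
z	-	-	+	+	-	-	-	+	+	-	-	+	+	-	-	-	-	-	-	0	-
ʃ	-	-	+	+	-	-	-	+	-	-	-	-	+	+	-	-	-	-	-	0	-
ʒ	-	-	+	+	-	-	-	+	+	-	-	-	+	+	-	-	-	-	-	0	-
x	-	-	+	+	-	-	-	-	-	-	-	-	-	0	-	+	-	+	-	0	-
h	-	-	-	+	-	-	-	-	-	+	-	0	0	0	0	0	0	0	0	0	-
ɦ	-	-	-	+	-	-	-	-	+	+	-	0	0	0	0	0	0	0	0	0	-
ç	-	-	+	+	-	-	-	-	-	-	-	-	-	0	-	+	-	-	-	0	-
m	-	+	+	-	-	-	+	-	+	-	-	+	-	0	+	-	-	-	-	0	-
n	-	+	+	-	-	-	+	-	+	-	-	+	+	-	-	-	-	-	-	0	-
ɲ	-	+	+	-	-	-	+	-	+	-	-	-	+	+	-	+	-	-	-	0	-
r	-	+	+	+	-	-	-	-	+	-	-	+	+	-	-	-	-	-	-	0	-
r̝	-	-	+	+	-	-	-	+	+	-	-	+	+	-	-	-	-	-	-	0	-
l	-	+	+	+	-	+	-	-	+	-	-	+	+	-	-	-	-	-	-	0	-
j	-	+	-	+	-	-	-	-	+	-	-	-	-	0	-	+	-	-	-	+	-
a	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	+	+	-	-	-
ɛ	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	-	-	-	-	-
e	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	-	-	-	+	-
i	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	+	-	-	-	+	-
ɪ	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	+	-	-	-	-	-
o	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	-	+	+	+	-
u	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	+	-	+	+	+	-
aː	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	+	+	-	+	+
ɛː	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	-	-	-	+	+
iː	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	+	-	-	-	+	+
oː	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	-	-	+	+	+	+
uː	+	+	-	+	-	-	-	0	+	-	-	0	-	0	-	+	-	+	+	+	+
WEIGHT	1.0	1.0	1.0	0.125	0.125	0.125	0.125	1.0	0.25	0.125	0.125	0.25	0.125	0.25	0.125	0.5	0.125	1.0	0.125	0.5	0.125
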