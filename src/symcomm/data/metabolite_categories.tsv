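# base metabolite id (compartment suffix stripped)	category
# Editable lookup used for binning ecology outputs; unlisted ids -> "other".
ala	amino-acid
dala	amino-acid
arg	amino-acid
asn	amino-acid
asp	amino-acid
cys	amino-acid
gln	amino-acid
glu	amino-acid
gly	amino-acid
his	amino-acid
hcys	amino-acid
ile	amino-acid
leu	amino-acid
lys	amino-acid
met	amino-acid
orn	amino-acid
phe	amino-acid
pro	amino-acid
ser	amino-acid
thr	amino-acid
trp	amino-acid
tyr	amino-acid
val	amino-acid
dap	amino-acid
glc	carbon
glyc	carbon
ac	carbon
acald	carbon
actn	carbon
akg	carbon
btd	carbon
cit	carbon
etoh	carbon
fald	carbon
form	carbon
fru	carbon
glyclt	carbon
lac	carbon
mal	carbon
mglx	carbon
pyr	carbon
succ	carbon
succoa	carbon
dump	nucleotide
damp	nucleotide
dcmp	nucleotide
dgmp	nucleotide
ura	nucleotide
uri	nucleotide
ade	nucleotide
gua	nucleotide
btn	vitamin-cofactor
coa	vitamin-cofactor
nmn	vitamin-cofactor
pydx5p	vitamin-cofactor
ribflv	vitamin-cofactor
thf	vitamin-cofactor
thm	vitamin-cofactor
nh4	inorganic
no3	inorganic
po4	inorganic
so4	inorganic
h2o	inorganic
h	inorganic
o2	inorganic
co2	inorganic
pi	inorganic
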