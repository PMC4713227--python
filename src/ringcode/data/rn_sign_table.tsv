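gene	sensilla	direction	confidence	provenance
Or67d	at1	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
Or23a	at2	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
Or2a	at3	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
Or47b	at4	up	text	"approximately 60 Or47b ORNs are found in wild type flies, and this number is increased to ~90 in rn mutants"
Or88a	at4	up	text	"Neurons from at4 sensilla in the trichoid zone ... are all expanded"
Or65a	at4	up	text	"Neurons from at4 sensilla in the trichoid zone ... are all expanded"
Gr21a	ab1	up	text	"ab1 and ab9 in the basiconic zone are all expanded"
Or92a	ab1	up	text	"ab1 and ab9 in the basiconic zone are all expanded"
Or85a	ab2	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
Or22a	ab3	up	figure_only	"ab3 behaves similarly to the sensilla subtypes from the center R(7) in some genetic manipulations"
Or56a	ab4	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
Or82a	ab5	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
Or49b	ab6	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
Or98a	ab7	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
Or9a	ab8	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
Or67b	ab9	up	text	"ab1 and ab9 in the basiconic zone are all expanded"
Or67a	ab10	down	text	"Or49a, which pairs with Or67a in ab10 sensilla, is downregulated"
Or49a	ab10	down	text	"Or49a, which pairs with Or67a in ab10 sensilla, is downregulated"
IR31a	ac1	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
IR41a	ac2	up	text	"ac2 in the coeloconic zone ... are all expanded"
Or35a	ac3	unchanged	text	"at2, ab2, ab4, ab6, ab8, and ac3 are rn-negative and unaffected in rn mutants"
IR84a	ac4	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
Or13a	ai1	down	text	"at the expense of specific ORNs in rn-positive sensilla subtypes"
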