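# Sentence templates for the synthetic corpus generator.
# Columns (tab-separated): type, template, gold relations.
# Types: POS = connectivity statement (gold relations in col 3),
# NEG = co-mention without connection, HYP = hedged/hypothetical
# co-mention (labeled unconnected), CIT = citation-like distractor,
# TAB = table-like distractor.
POS	The {A} receives projections from both the {B} and the {C}.	A-B,A-C
POS	Cells in the {A} were found to project to the {B}.	A-B
POS	The {A} sends dense projections to the {B}.	A-B
POS	A pathway from the {A} to the {B} has been described.	A-B
POS	Connections between the {A} and the {B} were observed.	A-B
POS	The {A} projects to the {B} and the {C}.	A-B,A-C
POS	Efferents from the {A} to the {B} were labeled.	A-B
POS	The {A} receives inputs from the {B}.	A-B
NEG	The {A} and the {B} were dissected and examined separately.
NEG	Neurons in the {A} and the {B} express the receptor at high levels.
NEG	The {A} appeared larger than the {B} in adult animals.
NEG	Staining was stronger in the {A} than in the {B}.
HYP	It has been proposed that the {A} may influence the {B} through an unknown pathway.
CIT	Methods followed earlier descriptions (Johnson and Smith, 1997).
TAB	12 34 0.56 78 90 1.2 3456 7.8 9 10
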