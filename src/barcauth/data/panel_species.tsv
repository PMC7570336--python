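# Restricted adulterant panel: close relatives, commercial species and known adulterants
# of Hypericum perforatum. Flags: REL close relative (Section Hypericum), MPNS medicinal
# reference listed, CULT ornamental/cultivated, ADULT reported adulterant.
name	attribution	section	robson_clade	meseguer_clade	REL	MPNS	CULT	ADULT
Hypericum acmosepalum	N.Robson	Ascyreia	3	D				Y
Hypericum androsaemum	L.	Androsaemum	5	C		Y	Y	Y
Hypericum ascyron	L.	Roscyna	7	D		Y		Y
Hypericum athoum	Boiss. & Orph	Adenosepalum	unknown	unknown			Y
Hypericum attenuatum	Fisch. ex Choisy	Hypericum	9	E	Y
Hypericum barbatum	Jacq.	Drosocarpium	13	E				Y
Hypericum calycinum	L.	Ascyreia	3	D		Y	Y
Hypericum crux-andreae	(L.) Crantz	Myriandra	20	B		Y		Y
Hypericum delphicum	Boiss. & Heldr.	Adenosepalum	27	E
Hypericum elegans	Stephan ex Willd.	Hypericum	unknown	unknown	Y	Y
Hypericum hirsutum	L.	Taeniocarpium	18	E				Y
Hypericum japonicum	Thunb.	Trigynobrathys	30	B		Y	Y
Hypericum kouytchense	H.Lev	Ascyreia	3	D			Y
Hypericum maculatum	Crantz	Hypericum	9	E	Y	Y		Y
Hypericum montanum	L.	Adenosepalum	27	E				Y
Hypericum olympicum	L.	Oligostema	14	E			Y
Hypericum patulum	Thunb.	Ascyreia	3	D		Y	Y	Y
Hypericum perforatum	L.	Hypericum	9	E		Y	Y
Hypericum tetrapterum	Fr.	Hypericum	9	E	Y	Y	Y	Y
Hypericum undulatum	Schousb. ex Willd.	Hypericum	9	E	Y			Y
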