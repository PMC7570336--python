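# Lithuanian field-collection character table (transcribed fixture; coordinates 1-based inclusive)
# its_result: Yes = matched the H. perforatum ITS reference; No = sequence obtained but failed
# (its_closest names the adulterant reference the failed sequence matched, if any); blank = no ITS data.
# stem_class: L long, S short, Sa short with AAA loop ('s' tolerated as S); rbcl_label per the rbcLa key.
sample_id	nominal_species	its_result	its_closest	stem_class	rbcl_label
mac 01	Hypericum maculatum	No	Hypericum maculatum	L	1
mac 02	Hypericum maculatum	No	Hypericum maculatum	L	1(p)
mac 03	Hypericum maculatum	No	Hypericum maculatum	L	1p
mac 04	Hypericum maculatum	No	Hypericum maculatum	L	1p
mac 05	Hypericum maculatum			L	1p
mac 06	Hypericum maculatum	No	Hypericum maculatum	L	1-2
mac 07	Hypericum maculatum			L	1
mac 08	Hypericum maculatum	No	Hypericum maculatum	L	1p
mac 09	Hypericum maculatum	No	Hypericum maculatum	L	1
mac 10	Hypericum maculatum			L	1(p)
mac 11	Hypericum maculatum			S	1p
mac 12	Hypericum maculatum	No	Hypericum maculatum	L	1p
mac 13	Hypericum maculatum	No	Hypericum maculatum	L	1p
mac 14	Hypericum maculatum	No	Hypericum maculatum	L	1
mac 15	Hypericum maculatum	No	Hypericum maculatum	s	1p
mac 16	Hypericum maculatum	No	Hypericum maculatum	L	1
perf 01	Hypericum perforatum			S	1p
perf 02	Hypericum perforatum	Yes		S	1-2
perf 03	Hypericum perforatum	No		Sa	1
perf 04	Hypericum perforatum	Yes		S	1p
perf 05	Hypericum perforatum			S	1p
perf 06	Hypericum perforatum			L	1p
perf 07	Hypericum perforatum	Yes		S	1p
perf 08	Hypericum perforatum	Yes		S	1
perf 09	Hypericum perforatum	No		S	1p
perf 10	Hypericum perforatum			S	1p
perf 11	Hypericum perforatum	Yes		S	1
perf 12	Hypericum perforatum			S	1p
perf 13	Hypericum perforatum	No		Sa	1p
perf 14	Hypericum perforatum			S	1p
perf 15	Hypericum perforatum			L	1p
perf 16	Hypericum perforatum	Yes		S	1p
perf 17	Hypericum perforatum	Yes		S	1p
perf 18	Hypericum perforatum	Yes		Sa	1p
perf 19	Hypericum perforatum	Yes		Sa	1p
perf 20	Hypericum perforatum	Yes		Sa	1p
perf 21	Hypericum perforatum	Yes		S	1p
perf 22	Hypericum perforatum			L	1(p)
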