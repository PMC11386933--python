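id	log2fc	pvalue	regulation
hsa-miR-206	-6.862038047	0.002496363	DOWN
hsa-miR-6747-3p	5.742275748	0.008604406	UP
hsa-miR-586	5.70016225	0.006725859	UP
miR-107-z	-5.374459919	0.04231448	DOWN
miR-885-y	5.318557873	0.026137781	UP
miR-3944-x	-5.12983251	0.021967984	DOWN
hsa-let-7a-2-3p	-3.673119112	0.008073136	DOWN
miR-4466-z	-3.275503758	0.036881144	DOWN
miR-326-z	3.156659061	0.007687275	UP
miR-9985-z	-2.874431932	0.01120557	DOWN
miR-196-y	2.645873775	0.03802994	UP
hsa-miR-3126-5p	-2.599843448	0.049289742	DOWN
novel-m0142-5p	-2.499521252	0.022049291	DOWN
miR-218-x	-2.48577105	0.023702183	DOWN
novel-m0118-3p	2.369243411	0.025500452	UP
hsa-miR-1260a	-2.338655004	0.026991179	DOWN
hsa-miR-3128	-2.001403855	0.026759362	DOWN
hsa-miR-10b-5p	1.852745152	0.014738408	UP
miR-21-z	-1.812351653	0.017354613	DOWN
hsa-miR-150-5p	1.749865396	0.010573319	UP
hsa-miR-3074-5p	-1.656512816	0.013318925	DOWN
miR-188-x	1.598706578	0.041051289	UP
hsa-miR-486-5p	1.48383397	0.035917054	UP
novel-m0037-3p	1.458954285	0.043017226	UP
hsa-miR-451a	1.456351917	0.008826723	UP
novel-m0039-3p	1.448933074	0.035806501	UP
novel-m0040-3p	1.448933074	0.035836655	UP
novel-m0041-3p	1.448933074	0.035802396	UP
novel-m0042-3p	1.448933074	0.035755084	UP
novel-m0078-5p	1.407254102	0.046943548	UP
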