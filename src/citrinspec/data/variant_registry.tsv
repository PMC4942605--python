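canonical_id	protein_effect	category	location_label	aliases
c.2T>C	p.Met1_Phe34del	pathogenic-SNP	Ex1	g.2T>C
r.16-212dup		aberrant-transcript	Ex2_3	r.16_212dup
c.72T>A	p.Y24X	nonsense	Ex3
c.103A>G	p.M35V	missense	Ex3
c.265delG	p.D89fs94X	deletion	Ex4
c.329-1687_c.468+3865del	p.E110fs127X	deletion	Ex5
[c.329-154_c.468+2352del2646;c.468+2392_c.468+2393ins23]	p.E110fs127X	complex	Ex5
IVS4ins6kb	p.E110fs127X	insertion	Ex5
c.475C>T	p.Q159X	nonsense	Ex6
c.493C>T	p.Q165X	nonsense	Ex6
c.495delA	p.Q165fs195X	deletion	Ex6
c.550C>T	p.R184X	nonsense	Ex6
IVS6+5G>A	p.V260fs212X	splice-site	IVS6
c.754G>A	p.E252K	splice-site	Ex7
c.755-1G>C	p.252fs269X	deletion	IVS7	IVS7-1G>C
c.775C>T	p.Q259X	nonsense	Ex8
c.790G>A	p.V264I	missense	Ex8
c.847G>T	p.G283X	nonsense	Ex8
c.845_c.848+1delG	p.D283fsX285	deletion	Ex8
c.851_854del4	p.R284fs286X	deletion	Ex9
c.933_c.933+1insGCAG	p.A312fsX317	insertion	Ex9	c.933+1_c.933+2insCAGG
c.955C>T	p.R319X	nonsense	Ex10	c.955G>A
c.998G>A	p.G333D	missense	Ex10
c.1019_1177+893del	p.340_392del	deletion	Ex11	1019_1177+893del
c.1048G>A	p.D350N	missense	Ex11
c.1063C>G	p.R355G	missense	Ex11
c.1064G>A	p.R355Q	missense	Ex11
c.1078C>T	p.R360X	nonsense	Ex11
c.1092_1095delT	p.F365fs407X	deletion	Ex11	1092-1095delT
IVS11+1G>A	p.340_392del	splice-site	IVS11
c.1215G>T	p.K405N	missense	Ex12
c.1231G>A	p.V411M	missense	Ex13
c.1364G>T	p.R455L	missense	Ex14
c.1381G>T	p.E461X	nonsense	Ex14
c.1399C>T	p.R467X	nonsense	Ex14
c.1452+1G>A	p.A438_K484del	splice-site	Ex14
c.1622C>A	p.A541D	missense	Ex16
c.1638_1660dup	p.A554fs570X	duplication	Ex16
c.1706_1707delTA	p.S331fsX363	deletion	Ex16
IVS16ins3kb	p.A584fs585X	insertion	IVS16
c.1775A>C	p.Q592P	missense	Ex17
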