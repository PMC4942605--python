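identity	north	border	south
c.2T>C	0.00	0.00	0.77
r.16-212dup	0.00	0.00	0.26
c.72T>A	0.00	1.23	0.00
c.103A>G	0.00	0.00	0.26
c.265delG	0.00	0.00	0.26
c.329-1687_c.468+3865del	0.00	0.00	0.26
[c.329-154_c.468+2352del2646;c.468+2392_c.468+2393ins23]	0.00	1.23	0.00
IVS4ins6kb	1.82	2.47	1.28
c.475C>T	0.00	1.23	0.00
c.493C>T	0.00	1.23	0.00
c.495delA	0.00	1.23	0.00
c.550C>T	0.00	1.23	0.51
IVS6+5G>A	3.64	8.64	7.91
c.754G>A	1.82	0.00	0.26
c.755-1G>C	1.82	0.00	0.00
c.775C>T	0.00	2.47	0.00
c.790G>A	0.00	0.00	0.26
c.847G>T	0.00	0.00	0.26
c.845_c.848+1delG	0.00	0.00	0.26
c.851_854del4	27.27	44.44	65.56
c.933_c.933+1insGCAG	1.82	0.00	0.00
c.955C>T	3.64	0.00	0.51
c.998G>A	0.00	0.00	0.26
c.1019_1177+893del	1.82	0.00	0.00
c.1048G>A	0.00	0.00	1.02
c.1063C>G	0.00	0.00	0.51
c.1064G>A	0.00	0.00	0.51
c.1078C>T	3.64	0.00	0.26
c.1092_1095delT	1.82	0.00	0.51
IVS11+1G>A	5.45	2.47	0.51
c.1215G>T	1.82	0.00	0.00
c.1231G>A	0.00	0.00	0.26
c.1364G>T	3.64	0.00	0.00
c.1381G>T	1.82	0.00	0.00
c.1399C>T	0.00	6.17	0.77
c.1452+1G>A	0.00	0.00	0.26
c.1622C>A	0.00	1.23	0.00
c.1638_1660dup	16.36	7.41	7.65
c.1706_1707delTA	0.00	1.23	0.00
IVS16ins3kb	20.00	16.05	7.40
c.1775A>C	0.00	0.00	0.26
?	1.82	0.00	1.28
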