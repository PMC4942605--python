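genotype	north	border	south
c.851_854del4/c.851_854del4	4.35	28.57	49.20
c.1638_1660dup/c.1638_1660dup	4.35	2.86	1.60
IVS6+5G>A/IVS6+5G>A	0.00	0.00	0.53
IVS16ins3kb/IVS16ins3kb	8.70	2.86	1.60
c.851_854del4/c.1638_1660dup	8.70	0.00	8.02
c.851_854del4/IVS6+5G>A	0.00	5.71	9.09
c.851_854del4/IVS16ins3kb	21.74	14.29	8.56
c.851_854del4/c.103A>G(p.M35V)	0.00	0.00	0.53
c.851_854del4/IVS4ins6kb	4.35	0.00	1.60
c.851_854del4/c.329-1687_c.468+3865del	0.00	0.00	0.53
c.851_854del4/c.550C>T(p.R184X)	0.00	0.00	0.53
c.851_854del4/c.775C>T(p.Q259X)	0.00	2.86	0.00
c.851_854del4/c.847G>T(p.G283X)	0.00	0.00	0.53
c.851_854del4/c.955G>A(p.R319X)	4.35	0.00	0.00
c.851_854del4/c.998G>A(p.G333D)	0.00	0.00	0.53
c.851_854del4/c.1019_1177+893del	4.35	0.00	0.00
c.851_854del4/c.1048G>A(p.D350N)	0.00	0.00	1.07
IVS6+5G>A/c.1064G>A(p.R355Q)	0.00	0.00	1.07
c.851_854del4/c.1078C>T(p.R360X)	0.00	0.00	0.53
c.851_854del4/c.1092_1095delT	0.00	0.00	0.53
c.851_854del4/c.1215G>T(p.K405N)	4.35	0.00	0.00
c.851_854del4/c.1231G>A(p.V411M)	0.00	0.00	0.53
c.851_854del4/c.1399C>T(p.R467X)	0.00	8.57	1.07
c.851_854del4/c.1775A>C(p.Q592P)	0.00	0.00	0.53
c.1638_1660dup/IVS6+5G>A	0.00	2.86	2.14
c.1638_1660dup/IVS16ins3kb	4.35	2.86	1.60
c.1638_1660dup/c.550C>T(p.R184X)	0.00	2.86	0.00
c.1638_1660dup/c.265delG	0.00	0.00	0.53
c.1638_1660dup/c.1063C>G(p.R355G)	0.00	0.00	0.53
c.1638_1660dup/IVS11+1G>A	4.35	0.00	0.00
c.1638_1660dup/c.1364G>T(p.R455L)	4.35	0.00	0.00
c.1638_1660dup/c.1381G>T(p.E461X)	4.35	0.00	0.00
IVS6+5G>A/IVS16ins3kb	0.00	2.86	1.07
IVS6+5G>A/c.955G>A(p.R319X)	4.35	0.00	1.07
IVS6+5G>A/IVS11+1G>A	0.00	2.86	0.00
IVS6+5G>A/c.1399C>T(p.R467X)	0.00	0.00	0.53
IVS6+5G>A/IVS4ins6kb	0.00	2.86	0.00
IVS16ins3kb/[c.329-154_c.468+2352del2646;c.468+2392_c.468+2393ins23]	0.00	2.86	0.00
IVS16ins3kb/IVS11+1G>A	4.35	0.00	0.00
IVS16ins3kb/c.495delA	0.00	2.86	0.00
IVS16ins3kb/c.1048G>A(p.D350N)	0.00	0.00	1.07
IVS16ins3kb/c.1063C>G(p.R355G)	0.00	0.00	0.53
IVS16ins3kb/c.493C>T(p.Q165X)	0.00	2.86	0.00
g.2T>C/r.16_212dup	0.00	0.00	0.53
c.2T>C/c.790G>A(p.V264I)	0.00	0.00	0.53
IVS11+1G>A/c.845_c.848+1delG	0.00	0.00	0.53
IVS11+1G>A/c.1078C>T(p.R360X)	4.35	0.00	0.00
c.550C>T(p.R184X)/IVS4ins6kb	0.00	0.00	0.53
c.1399C>T(p.R467X)/IVS4ins6kb	0.00	2.86	0.00
1092-1095delT/c.754G>A	0.00	0.00	0.53
c.475C>T(p.Q159X)/c.1399C>T(p.R467X)	0.00	2.86	0.00
IVS7-1G>C/c.1364G>T(p.R455L)	4.35	0.00	0.00
c.775C>T(p.Q259X)/c.72T>A(p.Y24X)	0.00	2.86	0.00
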