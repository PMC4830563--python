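no	species	e1	e2	e3	e4	e5	e6	e7	e8	e9	e10	e11	e12	e13
1	Rifleman
2	Golden-collared manakin	d17, sd	ed	ed	ed	ed	ed	ed	ed	ed	ed	ed	ed
3	American crow	d1, ns	tl, d1, d2	5d69	ed	ed	ed	ed	ed	ed	ed	ed	tl, 5d27, d10, sd	5d54, d1
4	Hooded crow	d1, ns	tl, d1, d2	5d69	ed	ed	ed	ed	ed	ed	ed	ed	tl, 5d27, d10, sd	5d54, d1
5	Ground tit	d1, d2	tl, 5d25, ns, d2	5d69	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d55
6	Collared flycatcher	ns, d1	tl, ns, ns	5d64, ns	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d117
7	Zebra finch	d1, i1, ns	tl, ns, d1	5d64	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d32, 3d20
8	Atlantic canary	d1, ns	tl, d1, d1	5d64, ns	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d105, 3d35
9	Medium ground finch	d1, ns	tl, ns, d1	5d64, ns	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d105
10	White-throated sparrow	d11, d1, ns	tl, ns, d1	5d64, d2	ed	ed	ed	ed	ed	ed	ed	ed	ed	5d105
11	Kea	d5, d5, d1	ed	5d37, d8	sa, i4, i1	ed	ed	ed		ed	ed	ed	ed	ed
12	Budgerigar	d5	ed	sa, i1	sa, d7, i1	ed	ed	ed	sd	ed	ed	ed	ed	ed
13	Puerto Rican Amazon	d5, ns, ns, d14	ed	5d19	sa, d7, i1	ed	ed	ed		ed	ed	ed	ed	ed
14	Scarlet macaw	d5	ed	sa, i1	sa, d7, i1	ed	ed	ed	ns	ed	ed	ed	ed	ed
15	Saker falcon	d5, ns, sd	sa	sd	d1			ns, d1			ns	sa
16	Peregrine falcon	d5, ns, sd	sa	sd	d1			ns, d1		ns	sa
17	Red-legged seriema					ns	ed	ed			sa, sd
18	Downy woodpecker	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
19	Northern carmine bee-eater	d181	ed		ed	ed	ed	ed	ed	d7		ns, sd		sa, ns
20	Rhinoceros hornbill							d1
21	Bar-tailed trogon		sa, sd	5d58, ns, d2		i7	5d4, ns, ns	d10			sa			i1, ns, 3d21
22	Cuckoo roller		sa, ns		d1	sd	sa, ns		d2, sd		sa	d2		d76
23	Speckled mousebird	5d12, d1, sd	sd	d8	sa, ns, d2	sa, sd		sa, ns, ns		ed	ed	ns, ns	sa, sd
24	Barn owl
25	Turkey vulture
26	White-tailed eagle
27	Golden eagle
28	White-tailed tropicbird
29	Sunbittern	ed	ed	ns, d7	i1	sa, i1	sa, ns, ns		ed	ed	ed	ed	ed	ed
30	Red-throated loon
31	Emperor penguin			sa					i7		sd	ed	ed
32	Adelie penguin	ns							i2
33	Northern fulmar
34	Great cormorant	d5, d1, ns	d1		5d7, d7	ns	ns	ns		sd	ns, sd		ns, 3d4	i1, d11
35	Crested ibis	d5	ns, d1	i1										d4
36	Little egret	d5, ns	ns	sa, ns, sd	sa			ns		d7		i13, d1, ns, sd	ns	d7, d1
37	Killdeer							ed
38	East African crowned crane
39	Hoatzin
40	Red-crested turaco
41	MacQueen's bustard
42	Common cuckoo
43	Chuck-will's-widow
44	Anna's hummingbird		ed	ed				d8					3d59	ed
45	Flamingo
46	Great crested grebe
47	Rock pigeon	ns	d1, sd	sd	sd				d20		sa
48	Yellow-throated sandgrouse	d1, ns		ed		i1			ed	ed	ed			d2
49	Brown mesite	d5	ed	ed	ns		d1, d8	ns	ed	ns	sa	sd		ns
50	Mallard
51	Northern bobwhite	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
52	Japanese quail	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
53	Chicken	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
54	Wild turkey	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
55	Black grouse	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd	gd
56	White-throated tinamou
57	African ostrich
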