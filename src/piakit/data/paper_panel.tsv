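# Blocking-peptide panel for the EcoRI chain scan, as printed.
# printed_start/printed_end are the coordinates as published; a handful of
# rows carry typographic coordinate errors (see anomalies.tsv) and the
# toolkit re-derives authoritative intervals from the sequences themselves.
# category: original | staggered | deletion_N | deletion_C | short_N | short_M | short_C | randomized
id	category	parent_id	printed_start	printed_end	sequence
BP1	original		2	15	SNKKQSNRLTEQHK
BP2	original		12	23	EQHKLSQGVIGI
BP3	original		20	33	VIGIFGDYAKAHDL
BP4	original		34	47	AVGEVSKLVKKALS
BP5	original		48	60	NEYPQLAFRYRDS
BP6	original		61	74	IKKTEINEALKKID
BP7	original		73	84	IDPDLGGTLFVS
BP8	original		82	93	FVSNSSIKPDGG
BP9	original		89	102	KPDGGIVEVKDDYG
BP10	original		103	116	EWRVVLVAEAKHQG
BP11	original		116	127	GKDIINIRNGLL
BP12	original		123	135	RNGLLVGKRGDQD
BP13	original		135	146	DLMAAGNAIERS
BP14	original		146	157	SHKNISEIANFM
BP15	original		158	170	LSESHFPYVLFLE
BP16	original		170	181	EGSNFLTENISI
BP17	original		182	193	TRPDGRVVNLEY
BP18	original		194	206	NSGILNRLDRLTA
BP19	original		206	217	AANYGMPINSNL
BP20	original		216	228	NLCINKFVNHKDK
BP21	original		229	242	SIMLQAASIYTQGD
BP22	original		243	252	GREWDSKIMFEIMF
BP23	original		252	265	FEIMFDISTTSLRV
BP24	original		259	272	STTSLRVLGRDLFE
BP25	original		266	277	LGRDLFEQLTSK
BP1.5	staggered		8	19	NRLTEQHKLSQG
BP2.5	staggered		16	27	LSQGVIGIFGDY
BP3.5	staggered		28	39	AKAHDLAVGEVS
BP4.5	staggered		42	52	VKKALSNEYPQL
BP5.5	staggered		55	66	FRYRDSIKKTEI
BP6.5	staggered		65	79	EALKKIDPDLGG
BP7.5	staggered		78	88	GGTLFVSNSSI
BP8.5	staggered		86	96	SSIKPDGGIVE
BP9.5	staggered		97	109	VKDDYGEWRVVL
BP10.5	staggered		111	121	EAKHQGKDIIN
BP11.5	staggered		120	131	INIRNGLLVGKR
BP12.5	staggered		130	140	KRGDQDLMAAG
BP13.5	staggered		141	151	NAIERSHKNIS
BP14.5	staggered		152	163	EIANFMLSESHF
BP15.5	staggered		165	175	YVLFLEGSNFL
BP16.5	staggered		176	187	TENISITRPDGR
BP17.5	staggered		188	199	VVNLEYNSGILN
BP18.5	staggered		201	211	LDRLTAANYGM
BP19.5	staggered		223	234	PINSNLCINK
BP20.5	staggered		237	252	VNHKDKSIMLQA
BP21.5	staggered		246	257	IYTQGDGREWDS
BP22.5	staggered		212	221	DSKIMFEIMFD
BP19.5N	deletion_N	BP19.5	212	217	PINSNL
BP19.5C	deletion_C	BP19.5	216	221	NLCINK
BP6N	short_N	BP6	61	66	IKKTEI
BP6M	short_M	BP6	65	70	EINEAL
BP6C	short_C	BP6	69	74	ALKKID
BP7N	short_N	BP7	73	78	IDPDLG
BP7M	short_M	BP7	76	81	DLGGTL
BP7C	short_C	BP7	79	84	GTLFVS
BP9N	short_N	BP9	89	94	KPDGGI
BP9M	short_M	BP9	93	98	GIVEVK
BP9C	short_C	BP9	97	102	VKDDYG
BP10N	short_N	BP10	103	108	EWRVVL
BP10M	short_M	BP10	107	112	VLVAEA
BP10C	short_C	BP10	111	116	EAKHQG
BP11N	short_N	BP11	116	121	GKDIIN
BP11M	short_M	BP11	119	124	IINIRN
BP11C	short_C	BP11	121	127	IRNGLL
BP12N	short_N	BP12	124	129	NGLLVG
BP12M	short_M	BP12	126	132	LVGKRG
BP12C	short_C	BP12	130	135	KRGDQD
BP13N	short_N	BP13	135	140	DLMAAG
BP13M	short_M	BP13	138	143	AAGNAI
BP13C	short_C	BP13	141	146	NAIERS
BP14N	short_N	BP14	146	151	SHKNIS
BP14M	short_M	BP14	149	154	NISEIA
BP14C	short_C	BP14	152	157	EIANFM
BP15N	short_N	BP15	158	163	LSESHF
BP15M	short_M	BP15	161	166	SHFPYV
BP15C	short_C	BP15	165	170	YVLFLE
BP22N	short_N	BP22	243	248	GREWDS
BP22M	short_M	BP22	245	250	EWDSKI
BP22C	short_C	BP22	247	252	DSKIMF
BP7R1	randomized	BP7			VGLILSTGDFDP
BP7R2	randomized	BP7			DGLTPFSDVLGI
BP10R1	randomized	BP10			VEGQELAVKAHRWV
BP10R2	randomized	BP10			AGRKQEVHAVWVEL
BP13R1	randomized	BP13			EALDIAMGRNSA
BP13R2	randomized	BP13			LAMRGASIADEN
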