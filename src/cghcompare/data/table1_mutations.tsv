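sample_id	group	raw	predicted_deleterious	abundance	complex_flag	hotspot_flag
B107	BRCA1	G266E	true	NA	0	1
B109	BRCA1	R213X	true	NA	1	1
B109	BRCA1	H214Y	true	NA	1	1
B116	BRCA1	Y163C	true	NA	0	1
B118	BRCA1	NA	NA	NA	NA	NA
B119	BRCA1	NA	NA	NA	NA	NA
B122	BRCA1	239 insT	true	NA	1	0
B124	BRCA1	NA	NA	NA	NA	NA
B125	BRCA1	NA	NA	NA	NA	NA
B126	BRCA1	del 255	true	NA	1	0
B127	BRCA1	T55I	false	NA	0	0
B135	BRCA1	wild type	NA	NA	0	0
B137	BRCA1	224 splice G > A	true	NA	1	0
B141	BRCA1	wild type	NA	NA	0	0
B145	BRCA1	110 delC	true	NA	1	0
B145	BRCA1	Q100X	true	NA	1	0
B146	BRCA1	145 delG	true	NA	1	0
B146	BRCA1	Q104X	true	NA	1	0
B146	BRCA1	P98S	false	NA	1	0
B149	BRCA1	R273H	true	NA	0	1
B150	BRCA1	V216 M	true	NA	0	1
B150	BRCA1	P223 S	false	NA	0	1
B150	BRCA1	R290C	false	NA	0	1
B152	BRCA1	R175H	true	NA	0	1
B153	BRCA1	del 155-156	true	NA	1	0
B156	BRCA1	R248W	true	NA	0	1
B156	BRCA1	R280K	true	NA	0	1
B156	BRCA1	V218I	false	NA	0	1
B158	BRCA1	R282G	true	NA	0	1
B158	BRCA1	E326K	true	NA	0	1
B160	BRCA1	167 insA	true	NA	1	0
B161	BRCA1	R213X	true	NA	1	1
B161	BRCA1	R282W	true	NA	1	1
B161	BRCA1	P151R	true	NA	1	1
B162	BRCA1	NA	NA	NA	NA	NA
B164	BRCA1	258 delG	true	NA	1	0
B165	BRCA1	NA	NA	NA	NA	NA
B171	BRCA1	R306X	true	NA	1	0
C002	luminal-J	R248W	true	NA	0	1
C002	luminal-J	R110C	true	NA	0	1
C002	luminal-J	T55I	false	NA	0	1
C010	luminal-J	NA	NA	NA	NA	NA
C017	luminal-J	K305X	true	NA	1	0
C020	luminal-J	wild type	NA	NA	0	0
C022	luminal-J	NA	NA	NA	NA	NA
C025	luminal-J	P177L	true	NA	0	1
C027	luminal-J	NA	NA	NA	NA	NA
C028	luminal-J	wild type	NA	NA	0	0
C030	luminal-J	wild type	NA	NA	0	0
C034	luminal-J	wild type	NA	NA	0	0
C036	luminal-J	wild type	NA	NA	0	0
C037	luminal-J	NA	NA	NA	NA	NA
C042	luminal-J	P190L	false	NA	0	0
C044	luminal-J	wild type	NA	NA	0	0
C052	luminal-J	wild type	NA	NA	0	0
C057	luminal-J	P98L	false	NA	0	0
C060	luminal-J	H179R	true	NA	0	1
C060	luminal-J	T125M	false	NA	0	1
131	BLBC	239_240delCA	true	NA	1	0
135	BLBC	C242Y	true	NA	0	1
164	BLBC	W53X	true	NA	1	0
184	BLBC	183_184insC	true	NA	1	0
215	BLBC	110delC	true	NA	1	0
228	BLBC	IVS5-2 A > C (splice)	true	NA	1	0
230	BLBC	E221X	true	NA	1	0
238	BLBC	V173M	true	NA	0	1
241	BLBC	R196X	true	NA	1	0
268	BLBC	L252P	false	NA	0	0
269	BLBC	N131S	false	NA	0	0
270	BLBC	283insGC	true	NA	1	0
307	BLBC	218delGTG	true	NA	1	0
324	BLBC	I195T	true	NA	0	1
326	BLBC	155_156del	true	NA	1	0
330	BLBC	201delT	true	NA	1	0
332	BLBC	Q286K	true	NA	0	1
335	BLBC	R248W	true	NA	0	1
367	BLBC	wild type	NA	NA	0	0
377	BLBC	255_256delTCA	true	NA	1	0
398	BLBC	Y220C	true	NA	0	1
6	luminal-H	wild type	NA	NA	0	0
107	luminal-H	Q317X	true	NA	1	0
110	luminal-H	wild type	NA	NA	0	0
145	luminal-H	R273C	true	NA	0	1
157	luminal-H	R248W	true	NA	0	1
166	luminal-H	wild type	NA	NA	0	0
167	luminal-H	wild type	NA	NA	0	0
176	luminal-H	wild type	NA	NA	0	0
203	luminal-H	wild type	NA	NA	0	0
205	luminal-H	K132R	true	NA	0	1
214	luminal-H	wild type	NA	NA	0	0
220	luminal-H	wild type	NA	NA	0	0
231	luminal-H	wild type	NA	NA	0	0
240	luminal-H	H179R	true	NA	0	1
295	luminal-H	wild type	NA	NA	0	0
298	luminal-H	wild type	NA	NA	0	0
302	luminal-H	wild type	NA	NA	0	0
305	luminal-H	wild type	NA	NA	0	0
312	luminal-H	205delT	true	NA	1	0
318	luminal-H	R110L	true	NA	0	1
318	luminal-H	S127C	true	NA	0	1
322	luminal-H	wild type	NA	NA	0	0
329	luminal-H	wild type	NA	NA	0	0
346	luminal-H	wild type	NA	NA	0	0
354	luminal-H	P177R	true	NA	0	1
356	luminal-H	wild type	NA	NA	0	0
361	luminal-H	wild type	NA	NA	0	0
371	luminal-H	wild type	NA	NA	0	0
378	luminal-H	wild type	NA	NA	0	0
389	luminal-H	wild type	NA	NA	0	0
391	luminal-H	wild type	NA	NA	0	0
393	luminal-H	wild type	NA	NA	0	0
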