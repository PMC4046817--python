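# Curated survey of Sulfolobus solfataricus P2 genomic regions enriched in
# both Ss-LrpB- and LysM-specific ChIP-chip experiments: the relation of
# each (extended) Ss-LrpB region to the LysM region, motif presence calls
# for both factors, and the resulting co-occupancy class.  A trailing '*'
# on a motif call is a raw annotation footnote carried through verbatim.
target	peak_start	peak_stop	relation	overlap_pct	lrpb_motif	lysm_motif	co_class
Sso0154	129616	130620	inside	100	-	-	III
Sso5317	131930	133008	including		-	+	II
Ssot18	290428	291131	inside	100	+	-	I
Ssot28	589572	590362	overlap	89	-	+	II
Sso6904	835210	835839	inside	100	-	+	II
Sso1027	885479	886771	inside	100	+	-	I
Sso1114	960343	961574	including		-	-*	III
Sso1118	964702	966378	including		-	-*	III
Sso1135	974250	975551	overlap	99	+	-*	I
Sso1272	1095398	1097098	inside	100	+	-*	I
Sso1371	1206614	1207226	overlap	97	+	-*	I
Sso1389	1232759	1233642	overlap	99	+	-*	I
CRISPR4	1260282	1261337	including		+	-*	I
Sso1433	1286420	1286928	inside	100	+	-*	I
Sso1463	1321798	1323084	overlap	98	-	-*	III
Sso1890	1705187	1705830	inside	100	-	-*	III
Sso2043	1859092	1860291	overlap	75	-	+	II
Sso2159	1985046	1985784	inside	100	-	-*	III
Sso2233	2050931	2052374	including		+	-*	I
Sso2289	2099312	2099902	inside	100	-	-*	III
Sso2309	2111358	2112389	inside	100	-	-*	III
Sso2310	2113136	2114378	overlap	93	-	-*	III
Sso2334	2132622	2134455	including		-	+	II
Sso2404	2187776	2188318	inside	100	-	-*	III
Sso2678	2437317	2437768	overlap	96	-	-*	III
Sso2801	2561656	2562152	overlap	57	-	-*	III
Sso2833	2594520	2595831	overlap	96	-	-*	III
Sso3002	2742947	2743947	including		-	-*	III
Sso3072	2827204	2828448	overlap	94	+	-*	I
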