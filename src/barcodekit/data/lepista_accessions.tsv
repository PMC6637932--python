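sample_id	species	ITS	IGS	nLSU	mtSSU	tef1
SYAU-FUNGI-022	Lepista densifolia	MK116588	MK389519	-	MK389570	-
SYAU-FUNGI-023	Lepista irina	MK116589	MK389520	MK389546	MK389571	MK551215
SYAU-FUNGI-024	Lepista irina	MK116590	MK389521	MK389547	MK389572	MK551216
SYAU-FUNGI-025	Lepista irina	MK116591	-	MK389548	MK389573	-
SYAU-FUNGI-021	Lepista nuda	MH428843	MK389523	MK389549	MK389575	MK440311
SYAU-FUNGI-026	Lepista nuda	MK116594	-	-	-	MK440315
SYAU-FUNGI-017	Lepista nuda	MH428839	MK389524	MK389550	MK389576	MK440312
SYAU-FUNGI-019	Lepista nuda	MH428841	-	MK389551	MK389577	MK440313
SYAU-FUNGI-027	Lepista nuda	MK116593	MK389525	MK389552	MK389578	MK440314
SYAU-FUNGI-014	Lepista nuda	MH428836	MK389526	MK389553	MK389579	MK440315
SYAU-FUNGI-028	Lepista nuda	MK116595	-	MK389554	MK389580	MK440317
SYAU-FUNGI-029	Lepista nuda	MK116592	MK389522	-	MK389574	MK440310
SYAU-FUNGI-030	Lepista panaeola	MK116597	MK389527	-	MK389581	-
SYAU-FUNGI-031	Lepista panaeola	MK116598	-	-	-	-
SYAU-FUNGI-032	Lepista panaeola	MK116599	MK389529	-	MK389583	MK551218
SYAU-FUNGI-033	Lepista panaeola	MK116600	MK389530	MK389555	MK389584	-
SYAU-FUNGI-034	Lepista panaeola	MK116601	MK389531	MK389556	MK389585	-
SYAU-FUNGI-035	Lepista panaeola	MK116596	MK389528	MK389557	MK389582	MK551217
SYAU-FUNGI-036	Lepista saeva	MK116602	MK389532	MK389558	MK389586	-
SYAU-FUNGI-037	Lepista saeva	MK116603	MK389533	MK389559	MK389587	-
SYAU-FUNGI-038	Lepista saeva	MK116604	MK389534	MK389560	MK389588	-
SYAU-FUNGI-039	Lepista sordida	MK116605	MK389535	MK389561	MK389589	MK551219
SYAU-FUNGI-040	Lepista sordida	MK116606	MK389536	-	MK389590	-
SYAU-FUNGI-041	Lepista sordida	MK116607	MK389537	MK389563	MK389591	-
SYAU-FUNGI-042	Lepista sordida	MK116609	MK389539	MK389564	MK389594	MK551221
SYAU-FUNGI-043	Lepista sordida	MK116610	MK389540	MK389565	MK389593	MK551222
SYAU-FUNGI-044	Lepista sordida	MK116608	MK389538	MK389562	MK389592	MK551220
SYAU-FUNGI-045	Lepista sp 1	MK116611	-	-	-	MK440305
SYAU-FUNGI-046	Lepista sp 1	MK116612	-	MK389567	-	MK440306
SYAU-FUNGI-047	Lepista sp 1	MK116613	MK389541	MK389568	MK389597	MK440307
SYAU-FUNGI-048	Lepista sp 1	MK116614	MK389542	MK389566	MK389595	MK440308
SYAU-FUNGI-049	Lepista sp 1	MK116615	MK389543	-	MK389596	MK440309
SYAU-FUNGI-050	Lepista sp 2	MK116617	MK389544	-	-	-
SYAU-FUNGI-051	Lepista sp 2	MK116616	MK389545	MK389569	-	-
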