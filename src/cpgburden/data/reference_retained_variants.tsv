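sample_id	variant_id	gene	quality	in_repeat_region	consequence	intron_offset	in_last_exon	maf_supercontrols	maf_gnomAD	maf_1000Genomes	maf_ESP	maf_ExAC	clinvar	known_sequencing_error	known_pathogenic_whitelisted
HCC001	PMS2:c.1144+250_2175-1948del8907	PMS2	500	0	cnv_deletion	0	0	.	.	.	.	.	none	0	0
HCC002	NBN:c.657del5	NBN	812	0	frameshift	0	0	0.001	0.0009	.	.	0.001	pathogenic	0	1
HCC003	NBN:c.657del5	NBN	640	0	frameshift	0	0	0.001	0.0009	.	.	0.001	pathogenic	0	1
HCC004	NBN:c.657del5	NBN	733	0	frameshift	0	0	0.001	0.0009	.	.	0.001	pathogenic	0	1
HCC005	NBN:c.657del5	NBN	698	0	frameshift	0	0	0.001	0.0009	.	.	0.001	pathogenic	0	1
HCC006	FH:c.1127A>C	FH	521	0	missense	0	0	.	.	.	.	.	pathogenic	0	0
HCC007	RET:c.2304G>C	RET	587	0	missense	0	0	.	0.0001	.	.	.	pathogenic	0	0
HCC008	DMBT1:c.2177-2A>C	DMBT1	455	0	canonical_splice	-2	0	.	.	.	.	.	none	0	0
HCC009	DMBT1:c.4828+1G>A	DMBT1	602	0	canonical_splice	1	0	.	.	.	.	.	none	0	0
HCC010	DMBT1:c.4611C>G	DMBT1	514	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC011	RAD50:c.1875C>G	RAD50	590	0	stop_gained	0	0	.	.	.	.	.	likely_pathogenic	0	0
HCC012	RAD50:c.2043delC	RAD50	477	0	frameshift	0	0	.	.	.	.	.	pathogenic	0	0
HCC013	RAD50:c.2521del9	RAD50	503	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC014	ATRIP:c.1870del2	ATRIP	566	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC013	ATRIP:c.1152del4	ATRIP	489	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC015	BLM:c.1642C>T	BLM	611	0	stop_gained	0	0	0.0006	0.0004	.	.	.	pathogenic	0	0
HCC016	BLM:c.1642C>T	BLM	580	0	stop_gained	0	0	0.0006	0.0004	.	.	.	pathogenic	0	0
HCC017	ERCC2:c.2150C>G	ERCC2	542	0	missense	0	0	.	.	.	.	.	likely_pathogenic	0	0
HCC018	ERCC2:c.2150C>G	ERCC2	575	0	missense	0	0	.	.	.	.	.	likely_pathogenic	0	0
HCC019	LIG3:c.1283delT	LIG3	468	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC020	LIG3:c.799C>T	LIG3	529	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC021	MSH3:c.2686G>T	MSH3	618	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC022	MSH3:c.1480delA	MSH3	472	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC023	SLX4:c.4207G>T	SLX4	593	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC024	SLX4:c.4024delA	SLX4	486	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC025	AXIN1:c.64C>T	AXIN1	554	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC026	ERCC5:c.3285del10	ERCC5	507	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC027	ERCC6:c.537T>A	ERCC6	621	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC028	EXO1:c.1578del2	EXO1	498	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC029	FANCA:del16-17	FANCA	450	0	cnv_deletion	0	0	.	.	.	.	.	none	0	0
HCC030	FANCD2:c.990-1G>A	FANCD2	539	0	canonical_splice	-1	0	.	.	.	.	.	none	0	0
HCC031	FANCG:c.313G>T	FANCG	600	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC032	HOXB13:c.251G>A	HOXB13	574	0	missense	0	0	.	0.0021	.	0.0018	0.0023	pathogenic	0	0
HCC033	MCPH1:c.126del2	MCPH1	463	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC034	MDC1:c.6081delC	MDC1	515	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC035	MMP8:c.460G>T	MMP8	588	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC036	MLH3:c.3393dup2	MLH3	531	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC037	NHEJ1:c.169C>T	NHEJ1	609	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC038	PIK3CG:c.2519del2	PIK3CG	482	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC039	PMS1:c.1009insA	PMS1	557	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC040	RAD1:c.168del5	RAD1	495	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC041	RECQL5:c.2308C>T	RECQL5	612	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC042	SBDS:c.258+2T>C	SBDS	548	0	canonical_splice	2	0	.	.	.	.	.	none	0	0
HCC043	SETX:c.5074dup2	SETX	524	0	frameshift	0	0	.	.	.	.	.	none	0	0
HCC044	SMARCA4:c.859+1G>A	SMARCA4	596	0	canonical_splice	1	0	.	.	.	.	.	none	0	0
HCC045	TLR2:c.1339C>T	TLR2	567	0	stop_gained	0	0	.	.	.	.	.	none	0	0
HCC046	TLR4:c.261-1G>C	TLR4	538	0	canonical_splice	-1	0	.	.	.	.	.	none	0	0
HCC047	XRCC1:c.406dupT	XRCC1	561	0	frameshift	0	0	.	.	.	.	.	none	0	0
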