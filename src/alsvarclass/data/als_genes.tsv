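gene	als_locus	chromosome	omim	inheritance	oe_mis_upper	oe_lof_upper	pli	phenotypes	ref
SOD1	ALS1	21	147450	AD,(AR)	0.918	0.978	0.17	-	B31
ALS2	ALS2	2	606352	AR	0.871	0.516	<0.01	Infantile onset ascending spastic paralysis	B32
SETX	ALS4	9	608465	AD	1.054	0.296	0.95	Spinocerebellar ataxia	B33
SPG11	ALS5	15	610844	AR	1.163	0.812	<0.01	Charcot-Marie-Tooth disease axonal type 2X, spastic paraplegia 11 (AR), juvenile amyotrophic lateral sclerosis	B34,B35
FUS	ALS6	16	137070	AD,(AR)	0.737	0.237	0.99	Hereditary essential tremor	B36,B37
VAPB	ALS8	20	605704	AD	0.882	1.135	0.31	Spinal muscular atrophy, late-onset	B38
ANG	ALS9	14	105850	AD	1.172	1.893	0.28	-	B39
TARDBP	ALS10	1	605078	AD	0.385	0.275	0.98	FTD	B40,B41
FIG4	ALS11	6	609390	AD	0.831	1.24	<0.01	Charcot-Marie-Tooth disease, type 4J (AR); Yunis-Varon syndrome (AR)	B42
OPTN	ALS12	10	602432	AD,(AR)	0.994	1.256	<0.01	Open angle glaucoma	B43
VCP	ALS14	9	601023	AD	0.326	0.127	0.99	FTD, inclusion body myopathy, Paget's disease, Charcot-Marie-Tooth disease, type 2Y	B44
UBQLN2	ALS15	X	300264	XL	0.824	0.448	0.84	-	B45
SIGMAR1	ALS16	9	601978	AR	0.769	0.736	0.16	Juvenile amyotrophic lateral sclerosis, distal hereditary motor neuropathies	B46
CHMP2B	ALS17	3	609512	AD	1.072	1.216	0	FTD	B47
PFN1	ALS18	17	176610	AD	0.54	0.686	0.73	-	B48
ERBB4	ALS19	2	600543	AD	0.805	0.216	0.99	-	B49
HNRNPA1	ALS20	12	164017	AD	0.461	0.364	0.93	FTD, inclusion body myopathy, Paget's disease	B50
HNRNPA2B1	.	7	600124	AD	0.473	0.218	0.99	FTD, inclusion body myopathy, Paget's disease	B50
MATR3	ALS21	5	164015	AD	0.704	0.079	1	Distal myopathy with vocal cord and pharyngeal weakness	B51
TUBA4A	ALS22	2	191110	AD	0.51	0.62	0.15	-	B52
ANXA11	ALS23	10	602572	AD	1.143	0.98	<0.01	-	B53
NEK1	ALS24	4	604588	AD	0.948	0.864	<0.01	Short-rib thoracic dysplasia 6 with or without polydactyly (AR)	B54,B55
KIF5A	ALS25	12	602821	AD	0.652	0.252	0.99	Spastic paraplegia 10 (AD), neonatal intractable myoclonus	B19,B56
C9orf72	FTDALS1	9	614260	AD	1.065	1.468	<0.01	FTD	B14,B18
CHCHD10	FTDALS2	22	615903	AD	0.939	1.903	<0.01	Spinal muscular atrophy Jokela type, isolated mitochondrial myopathy, FTD	B57
SQSTM1	FTDALS3	5	601530	AD	1.359	0.745	0.01	FTD, inclusion body myopathy, Paget's disease, neurodegeneration with ataxia, dystonia, and gaze palsy, childhood-onset	B58
TBK1	FTDALS4	12	604834	AD	0.794	0.42	0.07	-	B59,B60
CCNF	FTDALS5	16	600227	AD	0.979	0.419	0.12	-	B61
ATP13A2	.	1	610513	AR	0.913	0.584	<0.01	Kufor-Rakeb syndrome, spastic paraplegia 78 (AR)	B62
ATP7A	.	X	300011	AD	0.883	0.216	0.99	Menkes disease, occipital horn syndrome, spinal muscular atrophy (X-linked 3)	B63
C21orf2	.	21	603191	AD	1.205	1.35	<0.01	Retinal dystrophy with macular staphyloma, axial spondylometaphyseal dysplasia	B20
CACNA1A	.	19	601011	AD	0.609	0.134	1	Early infantile epileptic encephalopathy, episodic ataxia, migraine familial hemiplegic, spinocerebellar ataxia 6	B64,B65
CYLD	.	16	605018	AD	0.612	0.204	0.99	FTD, familial cylindromatosis, Brooke-Spiegler syndrome, trichoepithelioma	B66
DAO	.	12	124050	AD	1.102	1.697	<0.01	Schizophrenia	B67
DCTN1	.	2	601143	AD	0.967	0.364	0.08	Perry syndrome (AD), neuronopathy, distal hereditary motor, type VIIB (AD)	B68
DNAJC7	.	17	601964	AD	0.621	0.28	0.99	-	B69
ERLIN1	.	10	611604	AR	0.635	0.473	0.64	Spastic paraplegia 62 (AR)	B70
ERLIN2	.	8	611605	AR,AD	0.709	0.833	<0.01	Spastic paraplegia 18 (AR)	B71
EWSR1	.	22	133450	.	0.718	0.278	0.99	Ewing sarcoma	B72
GARS	.	7	600287	AD	0.911	0.402	0.3	Distal hereditary motor neuronopathy	B73
GLE1	.	9	603371	AD	0.967	0.752	<0.01	Lethal congenital contracture syndrome 1 (AR); lethal arthrogryposis with anterior horn cell disease (AR)	B74
GLT8D1	.	3	618355	AD	0.993	1.134	<0.01	-	B75
GRN	.	17	138945	AD	1.049	0.483	0.06	FTD, neuronal ceroid lipofuscinosis, primary progressive aphasia	B76
MAPT	.	17	157140	AD	0.873	0.596	<0.01	FTD, Pick's disease, progressive supranuclear palsy	B77
NEFH	.	22	162230	.	1.008	1.064	<0.01	Charcot-Marie-Tooth disease, axonal type 2CC	B78,B79
PRPH	.	12	170710	AD	1.006	1.383	<0.01	-	B80
RAPGEF2	.	4	609530	AD	0.693	0.197	1	-	B81
SPAST	.	2	604277	AD	0.896	0.224	0.99	Spastic paraplegia 4 (AD)	B82
SPG7	.	16	602783	AD	1.196	1.651	<0.01	Spastic paraplegia 7 (AR)	B83
SS18L1	.	20	606472	AD	0.818	0.306	0.98	-	B84
TAF15	.	17	601574	AD	0.9	0.399	0.15	Chondrosarcoma, extraskeletal myxoid	B85
TIA1	.	2	603518	AD	0.694	0.443	0.26	Welander distal myopathy	B86
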