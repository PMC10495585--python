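# Published document-frequency ranking of the 20 most-used instruments
# (input table for threshold/percentage arithmetic).
# Columns: rank, canonical_name, count, printed_percentage.
1	Patient Health Questionnaire (PHQ)	177	15.94
2	Hospital Anxiety and Depression Scale (HADS)	130	11.71
3	Generalized Anxiety Disorder (GAD)	118	10.63
4	Depression, Anxiety and Stress Scale (DASS-21)	102	9.18
5	Impact of Event Scale (IES)	57	5.13
6	Self-Rating Anxiety Scale (SAS)	55	4.95
7	State-Trait Anxiety Scale (STAI)	41	3.69
8	Perceived Stress Scale (PSS)	36	3.24
9	Edinburgh Postnatal Depression Scale (EPDS)	23	2.07
10	Connor Davidson Resilience Scale (CD-RISC)	23	2.07
11	Pittsburgh Sleep Quality Index (PSQI)	23	2.07
12	UCLA 3-Item Loneliness scale	22	1.98
13	The PTSD Checklist for DSM-5 (PCL-5)	19	1.71
14	World Health Organization Well-Being Index	18	1.62
15	Coronavirus Anxiety Scale (CAS)	13	1.17
16	Self-Rating Depression Scale (SDS)	12	1.08
17	Secondary Traumatic Stress Scale (STSS)	11	0.99
18	Center for Epidemiologic Studies Depression Scale (CES-D)	10	0.90
19	General Health Questionnaire (GHQ-28)	10	0.90
20	EuroQol-5D questionnaire (EQ-5D)	10	0.90
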