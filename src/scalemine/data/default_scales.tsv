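# Default lexicon of pandemic-era mental-health scales.
# Columns: canonical_name <TAB> acronym <TAB> pipe-separated aliases.
Patient Health Questionnaire (PHQ)	PHQ	PHQ-9|PHQ-2|PHQ-4|Patient Health Questionnaire-9|Patient Health Questionnaire-2
Hospital Anxiety and Depression Scale (HADS)	HADS	HADS-A|HADS-D
Generalized Anxiety Disorder (GAD)	GAD	GAD-7|GAD-2|Generalized Anxiety Disorder-7|Generalized Anxiety Disorder 7-item scale
Depression, Anxiety and Stress Scale (DASS-21)	DASS-21	DASS|Depression, Anxiety and Stress Scale-21|Depression Anxiety Stress Scales
Impact of Event Scale (IES)	IES	IES-R|IES-6|Impact of Event Scale-Revised
Self-Rating Anxiety Scale (SAS)	SAS	Zung Self-Rating Anxiety Scale
State-Trait Anxiety Scale (STAI)	STAI	State-Trait Anxiety Inventory|STAI-S|STAI-T
Perceived Stress Scale (PSS)	PSS	PSS-10|PSS-4
Edinburgh Postnatal Depression Scale (EPDS)	EPDS
Connor Davidson Resilience Scale (CD-RISC)	CD-RISC	Connor-Davidson Resilience Scale|CD-RISC-10
Pittsburgh Sleep Quality Index (PSQI)	PSQI
UCLA 3-Item Loneliness scale		UCLA-3|UCLA Loneliness Scale|Three-Item Loneliness Scale
The PTSD Checklist for DSM-5 (PCL-5)	PCL-5	PTSD Checklist for DSM-5
World Health Organization Well-Being Index		WHO-5|WHO-5 Well-Being Index|World Health Organization Five Well-Being Index
Coronavirus Anxiety Scale (CAS)	CAS
Self-Rating Depression Scale (SDS)	SDS	Zung Self-Rating Depression Scale
Secondary Traumatic Stress Scale (STSS)	STSS
Center for Epidemiologic Studies Depression Scale (CES-D)	CES-D	Center for Epidemiological Studies-Depression Scale|CES-D Scale
General Health Questionnaire (GHQ-28)	GHQ-28	GHQ|GHQ-12|General Health Questionnaire-12
EuroQol-5D questionnaire (EQ-5D)	EQ-5D	EQ-5D-5L|EuroQol-5D
Maslach Burnout Inventory (MBI)	MBI
Insomnia Severity Index (ISI)	ISI
Hamilton Anxiety Scale (HAMA)	HAMA	Hamilton Anxiety Rating Scale
Hamilton Depression Scale (HAMD)	HAMD	Hamilton Depression Rating Scale|HDRS
Numeric Rating Scale (NRS)	NRS
PTSD Checklist-Civilian Version (PCL-C)	PCL-C
Negative Coping Styles Scale
State Anxiety Scale (S-Anxiety)	S-Anxiety
Risk Assessment Suicidality Scale (RASS)	RASS
Corona Disease Anxiety Scale (CDAS)	CDAS
COVID-19 Peritraumatic Distress Index (CPDI)	CPDI
COVID-19 Stress Scale (CSS)	CSS
Fear of COVID-19 Scale (FCV-19S)	FCV-19S
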