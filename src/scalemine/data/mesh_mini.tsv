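# Miniature MeSH tree (SYNTHETIC test/demo fixture).
# Descriptor names are real MeSH headings; tree numbers are plausible
# placements spanning the five semantic-category branches, not an
# authoritative NLM export. Format: name<TAB>tree number.
Adult	M01.060.116
Young Adult	M01.060.116.815
Middle Aged	M01.060.116.630
Aged	M01.060.116.100
Aged, 80 and over	M01.060.116.100.080
Adolescent	M01.060.057
Child	M01.060.406
Child, Preschool	M01.060.406.448
Infant	M01.060.703
Infant, Newborn	M01.060.703.520
Pregnant Women	M01.975
Mothers	M01.620
Students	M01.848
Students, Medical	M01.848.769
Health Personnel	M01.526.485
Nurses	M01.526.485.650
Physicians	M01.526.485.810
Medical Staff, Hospital	M01.526.485.610
Caregivers	M01.220
Inpatients	M01.643.485
Outpatients	M01.643.708
Survivors	M01.860
Cross-Sectional Studies	N05.715.360.775.175.250
Cross-Sectional Studies	N06.850.520.450.500.225
Longitudinal Studies	N05.715.360.775.175.500
Longitudinal Studies	N06.850.520.450.500.450
Prospective Studies	N05.715.360.775.175.600
Retrospective Studies	N05.715.360.775.175.700
Cohort Studies	N05.715.360.775.175
Follow-Up Studies	N05.715.360.775.175.450
Surveys and Questionnaires	N05.715.360.300.800
Pilot Projects	N05.715.360.325.700
Focus Groups	N06.850.520.445.300
Interviews as Topic	N06.850.520.445.500
Qualitative Research	N06.850.520.700
China	Z01.252.474.164
Italy	Z01.542.446
Turkey	Z01.252.245.500.900
United States	Z01.107.567.875
Spain	Z01.542.846
Brazil	Z01.107.757.176
France	Z01.542.323
Germany	Z01.542.315
India	Z01.252.474.557
Saudi Arabia	Z01.252.245.400.800
Bangladesh	Z01.252.474.134
United Kingdom	Z01.542.363
Iran	Z01.252.245.350
Japan	Z01.252.474.463
Canada	Z01.107.567.350
Depression	F01.145.126.350
Anxiety	F01.145.126.100
Stress, Psychological	F01.145.126.842
Mental Health	F01.100.508
Loneliness	F01.100.435
Burnout, Psychological	F01.145.126.190
Resilience, Psychological	F01.100.760
Fear	F01.470.132.450
Suicidal Ideation	F01.145.126.980.875
Quality of Life	F01.100.675
Pregnancy	G08.686.785.760
Exercise	G11.427.410.698
Sleep	G11.561.803
Feeding Behavior	G07.203.650.353
Time Factors	G01.910.857
Nutritional Physiological Phenomena	G07.203.650
Social Isolation	F01.145.813.810
Quarantine	N06.850.780.680
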