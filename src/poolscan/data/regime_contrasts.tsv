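protein_id	description	PF-C_FC	PF-C_P	UF-C_FC	UF-C_P	UF-PF_FC	UF-PF_P
P48375	12 kDa FK506-binding protein	1.01	0.91	1.10	0.03	1.08	0.05
O02649	60 kDa heat shock protein, mitochondrial	1.05	0.14	1.13	0.00	1.07	0.04
Q9VA91	40S ribosomal protein S7	0.97	0.03	1.00	0.96	1.03	0.04
B4IL76	40S ribosomal protein S3	0.96	0.30	0.92	0.03	0.96	0.26
B4II57	Protein Turandot C	1.12	0.67	0.49	0.02	0.43	0.01
P35128	Ubiquitin-conjugating enzyme E2 N	1.03	0.86	1.16	0.03	1.14	0.06
P29845	Heat shock 70 kDa protein cognate 5	1.05	0.32	1.11	0.03	1.06	0.18
B4II58	Protein Turandot A1/2	1.28	0.49	0.47	0.13	0.37	0.03
P02828	Heat shock protein 83	1.03	0.24	1.09	0.01	1.06	0.04
P62152	Calmodulin	0.63	0.05	0.60	0.04	0.95	0.96
P13060	Elongation factor 2	0.97	0.25	0.93	0.03	0.97	0.24
Q8I1F4	rRNA 2'-O-methyltransferase fibrillarin	0.92	0.01	0.96	0.10	1.04	0.15
Q8MMC4	Protein CDV3 homolog	0.81	0.15	0.68	0.05	0.84	0.33
Q24046	Sodium/potassium-transporting ATPase subunit beta-1	0.98	0.34	1.03	0.25	1.05	0.04
Q24388	Larval serum protein 2	1.22	0.28	1.42	0.04	1.17	0.32
Q8SY61	General odorant-binding protein 56d	1.21	0.08	1.27	0.03	1.05	0.75
P07182	Chorion protein S36	0.97	0.82	0.77	0.01	0.80	0.03
Q9VAI6	General odorant-binding protein 99b	1.23	0.14	1.78	0.00	1.44	0.00
P24511	Chorion protein S16	1.01	0.98	0.84	0.06	0.84	0.05
Q9V7N5	V-type proton ATPase subunit C	0.95	0.22	0.91	0.03	0.96	0.35
P04357	Metallothionein-1	1.09	0.77	1.44	0.03	1.33	0.07
P48598	Eukaryotic translation initiation factor 4E	1.04	0.42	0.94	0.17	0.90	0.03
P41073	Zinc finger protein on ecdysone puffs	0.95	0.19	0.92	0.04	0.97	0.50
Q9VPH7	Eukaryotic peptide chain release factor subunit 1	1.18	0.05	1.04	0.77	0.88	0.12
Q7KML2	Probable peroxisomal acyl-coenzyme A oxidase 1	1.11	0.05	1.09	0.08	0.99	0.94
Q27237	Protein tumorous imaginal disks, mitochondrial	1.15	0.02	1.14	0.03	0.99	0.97
O77237	Protein pellino	0.76	0.00	0.78	0.01	1.03	0.90
P16163	Uricase	1.02	0.99	0.53	0.01	0.52	0.01
Q9VAI1	Probable complex I intermediate-associated protein 30, mitochondrial	0.82	0.02	0.80	0.02	0.98	0.88
Q9VTY6	Ubiquitin-conjugating enzyme E2 C	1.19	0.02	1.10	0.21	0.92	0.22
Q9VVW8	ATP-dependent (S)-NAD(P)H-hydrate dehydratase	1.13	0.29	1.26	0.04	1.11	0.33
P42787	Carboxypeptidase D	1.12	0.01	1.01	0.86	0.91	0.02
O02437	Protein yellow	0.99	0.97	0.90	0.04	0.91	0.06
Q9I7T7	La-related protein CG11505	0.94	0.11	0.85	0.01	0.91	0.05
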