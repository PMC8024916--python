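allotype	haplotype	ALL	AFR	AMR	EUR	EAS	SAS
1	EPIGMKDRQ	6.1	0.5	12.1	14.0	0.0	7.6
2	ERIGMKDRQ	25.6	28.1	22.6	14.4	42.6	18.4
3	ERIGMKDRE	8.5	11.4	5.8	6.6	2.7	14.5
4	ERIGMRDRE	3.2	3.0	8.9	1.0	2.4	2.4
5	ERIDMRDRE	6.2	8.4	3.9	6.3	0.0	10.9
6	EPIGMRDRE	5.8	4.0	10.2	9.2	0.7	6.5
7	KPIGMRDRE	7.2	2.9	8.5	4.1	17.1	5.0
8	EPMGMRDRE	21.8	17.4	14.0	21.5	28.5	26.7
9	EPMGMRNRE	0.1	0.0	0.4	0.4	0.0	0.0
10	EPIGVRNQE	9.6	3.5	12.4	22.4	5.8	6.5
11	EPIDMRDRE	2.7	9.9	0.7	0.1	0.0	0.0
12	KPIDMRDRE	1.4	5.2	0.1	0.0	0.0	0.0
13	EPIGVRNRE	0.8	3.0	0.1	0.0	0.0	0.0
14	EPMGMRNQE	0.4	1.7	0.0	0.0	0.0	0.0
15	ERMGMRDRE	0.2	0.5	0.0	0.0	0.1	0.1
16	EPMGMRDRQ	0.12	0.0	0.0	0.0	0.0	0.6
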