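haplogroup	place	coordinates	observed_age_ky	observed_lo_ky	observed_hi_ky
L3	Khor Angar (Djibouti)	12°23´N-43°21´E	70.8	52.7	88.1
N1a3a	Damqawt (Yemen)	16°34´N-52°51´E	11.9	9.2	14.6
N3	Kerman (Iran)	30°00´N-58°00´E	11.9	4.0	20.3
N5	Nagpur (India)	21°08´N-79°05´E	35.7	19.8	51.5
N7	Phnom Penh (Cambodia)	11°00´N-104°00´E	36.4	22.5	50.9
N8	DaNang (Vietnam)	16°00´N-108°00´E	20.4	9.8	31.6
N22	Kuching (Malaysia)	01°34´N-110°20´E	17.0	8.8	25.5
N21	Samarinda (Indonesia)	01°31´S-118°00´E	17.5	8.7	26.6
S	Darwin (Australia)	12°28´S-130°50´E	46.8	37.0	56.9
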