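haplogroup	place	coordinates	observed_age_ky	observed_lo_ky	observed_hi_ky
L3	Khor Angar (Djibouti)	12°23´N-43°21´E	70.8	52.7	88.1
X	Krasnovodsk (Turkmenistan)	40°10´N-53°00´E	31.9	20.7	45.6
N1	Samarkanda (Uzbekistan)	39°37´N-66°58´E	51.9	37.1	68.3
N2	Almaty (Kazajistan)	43°13´N-76°51´E	48.3	31.5	69.2
A	Urumchi (China)	43°49´N-87°37´E	27.6	19.3	38.3
N11	Kunming (China)	24°53´N-102°49´E	75.9	48.4	104.9
N10	HoChiMinh (Vietnam)	10°49´N-106°49´E	66.4	39.2	93.4
N9	Taiyuan (China)	37°52´N-112°33´E	37.9	27.5	48.7
S	Darwin (Australia)	12°28´S-130°50´E	46.8	37.0	56.9
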