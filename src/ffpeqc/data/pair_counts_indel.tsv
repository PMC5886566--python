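pair	kit	n_ff	n_ffpe	n_pos	n_co	n_di
1	QIAamp	3609	3402	3176	3140	36
2	QIAamp	3612	3369	3169	3122	47
3	QIAamp	3610	3435	3193	3154	39
4	QIAamp	3624	3428	3168	3122	46
5	QIAamp	3762	3445	3178	3136	42
6	QIAamp	3770	3446	3212	3170	42
7	QIAamp	3749	3587	3315	3276	39
8	QIAamp	3712	3589	3239	3203	36
9	GeneRead	3609	3568	3258	3210	48
10	GeneRead	3612	3589	3267	3221	46
11	GeneRead	3612	3538	3240	3196	44
12	GeneRead	3610	3588	3267	3216	51
13	GeneRead	3624	3565	3251	3206	45
14	GeneRead	3624	3567	3271	3235	36
15	GeneRead	3762	3611	3293	3245	48
16	GeneRead	3770	3614	3336	3292	44
17	GeneRead	3749	3629	3311	3268	43
18	GeneRead	3712	3711	3346	3310	36
19	Maxwell	3723	2931	2740	2703	37
20	Maxwell	3770	2999	2826	2797	29
21	Maxwell	3763	2957	2791	2759	32
22	Maxwell	3732	2736	2593	2570	23
23	Maxwell	3600	2952	2779	2756	23
24	Maxwell	3635	2972	2788	2752	36
25	Maxwell	3651	3036	2839	2810	29
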