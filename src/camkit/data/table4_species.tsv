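species	scientific_name	group	dist_zf	dist_ch	pct_amp	pct_poly	is_source	exclude_poly
Zebra finch	Taeniopygia guttata	passerine	0	28	100	92	1	0
Berthelot's pipit	Anthus berthelotii	passerine	8.3	28	96	70	0	0
House sparrow	Passer domesticus	passerine	8.5	28	96	78	0	0
Chaffinch	Fringilla coelebs	passerine	10.0	28	96	83	0	0
Eurasian bullfinch	Pyrrhula pyrrhula	passerine	10.0	28	96	65	0	0
Great tit	Parus major	passerine	11.1	28	96	56	0	0
European blackbird	Turdus merula	passerine	11.7	28	83	60	0	0
Rifleman	Acanthisitta chloris	passerine	19.7	28	96	61	0	0
Leach's storm-petrel	Oceanodroma leucorhoa	non-passerine	21.6	28	96	56	0	0
Barn owl	Tyto alba	non-passerine	22.5	28	92	32	0	0
European roller	Coracias garrulus	non-passerine	25.0	28	96	39	0	0
Chicken	Gallus gallus	non-passerine	28.0	0	100	38	0	1
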