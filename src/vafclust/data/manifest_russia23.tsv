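sample_id	taxon	section	source
balsamifera_Dmitrovka_444	P. balsamifera	Tacamahaca	Dmitrovka, Moscow Region
balsamifera_Dmitrovka_445	P. balsamifera	Tacamahaca	Dmitrovka, Moscow Region
laurifolia_Novokuznetsk_1	P. laurifolia	Tacamahaca	Novokuznetsk
laurifolia_Novokuznetsk_2	P. laurifolia	Tacamahaca	Novokuznetsk
longifolia_Moscow_m	P. longifolia	Tacamahaca	Moscow
longifolia_Moscow_f	P. longifolia	Tacamahaca	Moscow
suaveolens_Irkutsk_1	P. suaveolens	Tacamahaca	Irkutsk
suaveolens_Irkutsk_2	P. suaveolens	Tacamahaca	Irkutsk
suaveolens_Novokuznetsk	P. suaveolens	Tacamahaca	Novokuznetsk
wobstii_Moscow	P. x wobstii	Tacamahaca	Moscow
deltoides_Moscow	P. deltoides	Aigeiros	Moscow
deltoides_Sevastopol	P. deltoides	Aigeiros	Sevastopol
canadensis_Moscow_1	P. x canadensis	Aigeiros	Moscow
canadensis_Moscow_2	P. x canadensis	Aigeiros	Moscow
canadensis_Voronezh	P. x canadensis	Aigeiros	Voronezh
nigra_Novokuznetsk_1	P. nigra	Aigeiros	Novokuznetsk
nigra_Novokuznetsk_2	P. nigra	Aigeiros	Novokuznetsk
nigra_Voronezh	P. nigra	Aigeiros	Voronezh
nigra_Bashkortostan	P. nigra	Aigeiros	Bashkortostan
petrovskoe_Moscow_1	P. x petrovskoe	Aigeiros x Tacamahaca	Moscow
petrovskoe_Moscow_2	P. x petrovskoe	Aigeiros x Tacamahaca	Moscow
rasumovskoe_Moscow	P. x rasumovskoe	Aigeiros x Tacamahaca	Moscow
sibirica_Moscow	P. x sibirica	Aigeiros x Tacamahaca	Moscow
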