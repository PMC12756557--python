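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
SRR21000001	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000002	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000003	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000004	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000005	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000006	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000007	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000008	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000009	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000010	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000011	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000012	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000013	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000014	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000015	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000016	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000017	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000018	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000019	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000020	P. trichocarpa	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000021	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000022	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000023	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000024	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000025	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000026	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000027	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000028	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000029	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000030	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000031	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000032	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000033	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000034	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000035	P. balsamifera	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000036	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000037	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000038	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000039	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000040	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000041	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000042	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000043	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000044	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000045	P. deltoides	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000046	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000047	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000048	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000049	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000050	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000051	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000052	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000053	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000054	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000055	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000056	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000057	P. nigra	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000058	P. suaveolens	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000059	P. suaveolens	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000060	P. suaveolens	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000061	P. suaveolens	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000062	P. suaveolens	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000063	P. simonii	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000064	P. simonii	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000065	P. simonii	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000066	P. lasiocarpa	Leuce	NCBI SRA (synthetic stand-in)
SRR21000067	P. lasiocarpa	Leuce	NCBI SRA (synthetic stand-in)
SRR21000068	P. ussuriensis	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000069	P. ussuriensis	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000070	P. pseudomaximowiczii	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000071	P. pseudomaximowiczii	Tacamahaca	NCBI SRA (synthetic stand-in)
SRR21000072	P. x canadensis	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000073	P. x canadensis	Aigeiros	NCBI SRA (synthetic stand-in)
SRR21000074	P. x canadensis	Aigeiros	NCBI SRA (synthetic stand-in)
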