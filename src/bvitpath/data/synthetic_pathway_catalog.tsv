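vitamin_code	metacyc_id	gene_accession	gene_symbol	threshold_override
B1	THISYN-PWY	P30136	thiC	
B1	THISYN-PWY	P30137	thiE	
B1	THISYN-PWY	P76422	thiD	
B1	THISYN-PWY	P30138	thiF	
B1	THISYN-PWY	P30139	thiG	
B1	THISYN-PWY	P30140	thiH	
B1	THISYN-PWY	O32583	thiS	
B1	THISYN-PWY	P0AGG0	thiL	
B1	THISYN-PWY	P77488	dxs	
B1	THISYN-PWY	P31550	thiB	
B2	RIBOSYN2-PWY	P0A7I7	ribA	
B2	RIBOSYN2-PWY	P0A7J0	ribB	
B2	RIBOSYN2-PWY	P25539	ribD	
B2	RIBOSYN2-PWY	P0AFU8	ribE	
B2	RIBOSYN2-PWY	P61714	ribH	
B2	RIBOSYN2-PWY	P0AG40	ribC	
B2	RIBOSYN2-PWY	P0A8I1	ribF	
B3	PYRIDNUCSYN-PWY	P11458	nadA	
B3	PYRIDNUCSYN-PWY	P10902	nadB	
B3	PYRIDNUCSYN-PWY	P30011	nadC	
B3	PYRIDNUCSYN-PWY	P0A752	nadD	
B3	PYRIDNUCSYN-PWY	P18843	nadE	
B5	PANTO-PWY	P31057	panB	
B5	PANTO-PWY	P31663	panC	
B5	PANTO-PWY	P0A790	panD	
B5	PANTO-PWY	P0A9J4	panE	
B6	PYRIDOXSYN-PWY	P0A794	pdxA	
B6	PYRIDOXSYN-PWY	P05459	pdxB	
B6	PYRIDOXSYN-PWY	P23721	serC	
B6	PYRIDOXSYN-PWY	P0A7D0	pdxJ	
B6	PYRIDOXSYN-PWY	P0AFI7	pdxH	
B6	PYRIDOXSYN-PWY	P0A6P9	epd	
B6	PYRIDOXSYN-PWY	P40191	pdxK	
B7	BIOTIN-BIOSYNTHESIS-PWY	P12995	bioA	
B7	BIOTIN-BIOSYNTHESIS-PWY	P12996	bioB	
B7	BIOTIN-BIOSYNTHESIS-PWY	P12999	bioC	
B7	BIOTIN-BIOSYNTHESIS-PWY	P13000	bioD	
B7	BIOTIN-BIOSYNTHESIS-PWY	P12998	bioF	
B7	BIOTIN-BIOSYNTHESIS-PWY	P13001	bioH	
B7	BIOTIN-BIOSYNTHESIS-PWY	P0A6E9	fabB	
B7	BIOTIN-BIOSYNTHESIS-PWY	P0A953	fabF	
B9	FOLSYN-PWY	P0A6C1	folE	
B9	FOLSYN-PWY	P0AC16	folB	
B9	FOLSYN-PWY	P26281	folK	
B9	FOLSYN-PWY	P0AC13	folP	
B9	FOLSYN-PWY	P08192	folC	
B9	FOLSYN-PWY	P0ABQ4	folA	
B9	FOLSYN-PWY	P28306	pabA	
B9	FOLSYN-PWY	P05041	pabB	
B9	FOLSYN-PWY	P0A9J8	pabC	
B9	FOLSYN-PWY	P60546	folX	
B12	PWY-5507	P0A9H5	cobA	
B12	PWY-5507	P31570	cbiA	
B12	PWY-5507	Q05590	cbiB	
B12	PWY-5507	P29946	cbiC	
B12	PWY-5507	P29947	cbiD	
B12	PWY-5507	P29948	cbiE	
B12	PWY-5507	P29949	cbiF	
B12	PWY-5507	P29950	cbiG	
B12	PWY-5507	P29951	cbiH	
B12	PWY-5507	P31571	cbiJ	
B12	PWY-5507	P31572	cbiK	
B12	PWY-5507	P31573	cbiL	
B12	PWY-5507	P31574	cbiM	
B12	PWY-5507	P31575	cbiN	
B12	PWY-5507	P31576	cbiO	
B12	PWY-5507	P31577	cbiP	
B12	PWY-5507	P31578	cbiQ	
B12	PWY-5507	P31579	cbiT	
B12	PWY-5507	P19934	cobU	
B12	PWY-5507	P39701	cobS	
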