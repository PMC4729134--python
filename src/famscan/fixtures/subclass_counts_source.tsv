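symbol	subclass	clade	subfamily
MADSD1a	MIKC_STAR	1	
MADSD1b	MIKC_STAR	1	
MADSD1c	MIKC_STAR	1	
MADSD2a	MIKC_STAR	2	
MADSD2b	MIKC_STAR	2	
MADSD3a	MIKC_STAR	3	
MADS1A1a	M_ALPHA	1	
MADS1A1b	M_ALPHA	1	
MADS1A1c	M_ALPHA	1	
MADS1A1d	M_ALPHA	1	
MADS1A1e	M_ALPHA	1	
MADS1A1f	M_ALPHA	1	
MADS1A1g	M_ALPHA	1	
MADS1A2a	M_ALPHA	2	
MADS1A2b	M_ALPHA	2	
MADS1A2c	M_ALPHA	2	
MADS1A2d	M_ALPHA	2	
MADS1A2e	M_ALPHA	2	
MADS1A2f	M_ALPHA	2	
MADS1A2g	M_ALPHA	2	
MADS1A2h	M_ALPHA	2	
MADS1A2i	M_ALPHA	2	
MADS1A3a	M_ALPHA	3	
MADS1A3b	M_ALPHA	3	
MADS1A3c	M_ALPHA	3	
MADS1A3d	M_ALPHA	3	
MADS1A3e	M_ALPHA	3	
MADS1A3f	M_ALPHA	3	
MADS1A3g	M_ALPHA	3	
MADS1G1a	M_GAMMA	1	
MADS1G1b	M_GAMMA	1	
MADS1G1c	M_GAMMA	1	
MADS1G1d	M_GAMMA	1	
MADS1G1e	M_GAMMA	1	
MADS1G1f	M_GAMMA	1	
MADS1G1g	M_GAMMA	1	
MADS1G1h	M_GAMMA	1	
MADS1G1i	M_GAMMA	1	
MADS1G1j	M_GAMMA	1	
MADS1G2a	M_GAMMA	2	
MADS1G2b	M_GAMMA	2	
MADS1G2c	M_GAMMA	2	
MADS1G2d	M_GAMMA	2	
MADS1G2e	M_GAMMA	2	
MADS1G2f	M_GAMMA	2	
MADS1G2g	M_GAMMA	2	
MADS1G2h	M_GAMMA	2	
MADS1G3a	M_GAMMA	3	
VviSOC1a	MIKC_C		SOC1
VviSOC1b	MIKC_C		SOC1
VviSOC1c	MIKC_C		SOC1
VviSVP1	MIKC_C		SVP
VviSVP2	MIKC_C		SVP
VviSVP3	MIKC_C		SVP
VviSVP4	MIKC_C		SVP
VviSVP5	MIKC_C		SVP
VviSVPS1	MIKC_C		SVP
VviSVPS2	MIKC_C		SVP
VviSVPS3	MIKC_C		SVP
VviSVPS4	MIKC_C		SVP
VviSVPS5	MIKC_C		SVP
VviAGL17a	MIKC_C		AGL17
VviAGL17b	MIKC_C		AGL17
VviAGL17c	MIKC_C		AGL17
VviAGL17d	MIKC_C		AGL17
VviBS1	MIKC_C		BS
VviBS2	MIKC_C		BS
VviBS3	MIKC_C		BS
VviAGL6a	MIKC_C		AGL6
VviAGL6b	MIKC_C		AGL6
VviTM8a	MIKC_C		TM8
VviTM8b	MIKC_C		TM8
VviAP1	MIKC_C		AP1/FUL
VviFUL1	MIKC_C		AP1/FUL
VviPI	MIKC_C		PI
VviAGL15a	MIKC_C		AGL15
VviSEP1	MIKC_C		SEP
VviSEP3	MIKC_C		SEP
VviAG1	MIKC_C		AG
VviAG2	MIKC_C		AG
VviFLC1	MIKC_C		FLC
VviFLC2	MIKC_C		FLC
MIKCC-u1	MIKC_C		unnamed
MIKCC-u2	MIKC_C		unnamed
MIKCC-u3	MIKC_C		unnamed
MIKCC-u4	MIKC_C		unnamed
MIKCC-u5	MIKC_C		unnamed
MIKCC-u6	MIKC_C		unnamed
MIKCC-u7	MIKC_C		unnamed
MIKCC-u8	MIKC_C		unnamed
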