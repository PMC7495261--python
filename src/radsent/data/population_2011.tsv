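prefecture	population
HOKKAIDO	5506419
AOMORI	1362820
IWATE	1314187
MIYAGI	2327006
AKITA	1074981
YAMAGATA	1157929
FUKUSHIMA	1990000
IBARAKI	2957706
TOCHIGI	1999422
GUNMA	2000514
SAITAMA	7207139
CHIBA	6214148
TOKYO	13195974
KANAGAWA	9058094
NIIGATA	2362158
TOYAMA	1087745
ISHIKAWA	1166309
FUKUI	802906
YAMANASHI	857459
NAGANO	2142167
GIFU	2070908
SHIZUOKA	3749274
AICHI	7416336
MIE	1847334
SHIGA	1413989
KYOTO	2632796
OSAKA	8861012
HYOGO	5581968
NARA	1395845
WAKAYAMA	995010
TOTTORI	585494
SHIMANE	712292
OKAYAMA	1940559
HIROSHIMA	2855045
YAMAGUCHI	1442428
TOKUSHIMA	780230
KAGAWA	992998
EHIME	1423406
KOCHI	757914
FUKUOKA	5079291
SAGA	846787
NAGASAKI	1417423
KUMAMOTO	1812575
OITA	1191430
MIYAZAKI	1130983
KAGOSHIMA	1698695
OKINAWA	1401066
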