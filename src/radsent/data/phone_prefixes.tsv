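prefix	prefecture
011	HOKKAIDO
017	AOMORI
019	IWATE
022	MIYAGI
018	AKITA
023	YAMAGATA
024	FUKUSHIMA
029	IBARAKI
028	TOCHIGI
027	GUNMA
048	SAITAMA
043	CHIBA
03	TOKYO
045	KANAGAWA
025	NIIGATA
0766	TOYAMA
076	ISHIKAWA
0776	FUKUI
055	YAMANASHI
026	NAGANO
058	GIFU
054	SHIZUOKA
052	AICHI
059	MIE
077	SHIGA
075	KYOTO
06	OSAKA
078	HYOGO
0742	NARA
073	WAKAYAMA
0857	TOTTORI
0852	SHIMANE
086	OKAYAMA
082	HIROSHIMA
083	YAMAGUCHI
0886	TOKUSHIMA
087	KAGAWA
089	EHIME
0888	KOCHI
092	FUKUOKA
0952	SAGA
095	NAGASAKI
096	KUMAMOTO
097	OITA
0985	MIYAZAKI
099	KAGOSHIMA
098	OKINAWA
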