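prefix	prefecture
001	HOKKAIDO
030	AOMORI
020	IWATE
980	MIYAGI
010	AKITA
990	YAMAGATA
960	FUKUSHIMA
310	IBARAKI
320	TOCHIGI
371	GUNMA
330	SAITAMA
260	CHIBA
100	TOKYO
220	KANAGAWA
950	NIIGATA
930	TOYAMA
920	ISHIKAWA
910	FUKUI
400	YAMANASHI
380	NAGANO
500	GIFU
420	SHIZUOKA
450	AICHI
514	MIE
520	SHIGA
600	KYOTO
530	OSAKA
650	HYOGO
630	NARA
640	WAKAYAMA
680	TOTTORI
690	SHIMANE
700	OKAYAMA
730	HIROSHIMA
753	YAMAGUCHI
770	TOKUSHIMA
760	KAGAWA
790	EHIME
780	KOCHI
810	FUKUOKA
840	SAGA
850	NAGASAKI
860	KUMAMOTO
870	OITA
880	MIYAZAKI
890	KAGOSHIMA
900	OKINAWA
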