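word	prefecture
北海道	HOKKAIDO
札幌市	HOKKAIDO
青森	AOMORI
青森県	AOMORI
青森市	AOMORI
岩手	IWATE
岩手県	IWATE
盛岡市	IWATE
岩手市	IWATE
宮城	MIYAGI
宮城県	MIYAGI
仙台市	MIYAGI
宮城市	MIYAGI
秋田	AKITA
秋田県	AKITA
秋田市	AKITA
山形	YAMAGATA
山形県	YAMAGATA
山形市	YAMAGATA
福島	FUKUSHIMA
福島県	FUKUSHIMA
福島市	FUKUSHIMA
茨城	IBARAKI
茨城県	IBARAKI
水戸市	IBARAKI
茨城市	IBARAKI
栃木	TOCHIGI
栃木県	TOCHIGI
宇都宮市	TOCHIGI
栃木市	TOCHIGI
群馬	GUNMA
群馬県	GUNMA
前橋市	GUNMA
群馬市	GUNMA
埼玉	SAITAMA
埼玉県	SAITAMA
さいたま市	SAITAMA
埼玉市	SAITAMA
千葉	CHIBA
千葉県	CHIBA
千葉市	CHIBA
東京	TOKYO
東京都	TOKYO
新宿区	TOKYO
神奈川	KANAGAWA
神奈川県	KANAGAWA
横浜市	KANAGAWA
神奈川市	KANAGAWA
新潟	NIIGATA
新潟県	NIIGATA
新潟市	NIIGATA
富山	TOYAMA
富山県	TOYAMA
富山市	TOYAMA
石川	ISHIKAWA
石川県	ISHIKAWA
金沢市	ISHIKAWA
石川市	ISHIKAWA
福井	FUKUI
福井県	FUKUI
福井市	FUKUI
山梨	YAMANASHI
山梨県	YAMANASHI
甲府市	YAMANASHI
山梨市	YAMANASHI
長野	NAGANO
長野県	NAGANO
長野市	NAGANO
岐阜	GIFU
岐阜県	GIFU
岐阜市	GIFU
静岡	SHIZUOKA
静岡県	SHIZUOKA
静岡市	SHIZUOKA
愛知	AICHI
愛知県	AICHI
名古屋市	AICHI
愛知市	AICHI
三重	MIE
三重県	MIE
津市	MIE
三重市	MIE
滋賀	SHIGA
滋賀県	SHIGA
大津市	SHIGA
滋賀市	SHIGA
京都	KYOTO
京都府	KYOTO
京都市	KYOTO
大阪	OSAKA
大阪府	OSAKA
大阪市	OSAKA
兵庫	HYOGO
兵庫県	HYOGO
神戸市	HYOGO
兵庫市	HYOGO
奈良	NARA
奈良県	NARA
奈良市	NARA
和歌山	WAKAYAMA
和歌山県	WAKAYAMA
和歌山市	WAKAYAMA
鳥取	TOTTORI
鳥取県	TOTTORI
鳥取市	TOTTORI
島根	SHIMANE
島根県	SHIMANE
松江市	SHIMANE
島根市	SHIMANE
岡山	OKAYAMA
岡山県	OKAYAMA
岡山市	OKAYAMA
広島	HIROSHIMA
広島県	HIROSHIMA
広島市	HIROSHIMA
山口	YAMAGUCHI
山口県	YAMAGUCHI
山口市	YAMAGUCHI
徳島	TOKUSHIMA
徳島県	TOKUSHIMA
徳島市	TOKUSHIMA
香川	KAGAWA
香川県	KAGAWA
高松市	KAGAWA
香川市	KAGAWA
愛媛	EHIME
愛媛県	EHIME
松山市	EHIME
愛媛市	EHIME
高知	KOCHI
高知県	KOCHI
高知市	KOCHI
福岡	FUKUOKA
福岡県	FUKUOKA
福岡市	FUKUOKA
佐賀	SAGA
佐賀県	SAGA
佐賀市	SAGA
長崎	NAGASAKI
長崎県	NAGASAKI
長崎市	NAGASAKI
熊本	KUMAMOTO
熊本県	KUMAMOTO
熊本市	KUMAMOTO
大分	OITA
大分県	OITA
大分市	OITA
宮崎	MIYAZAKI
宮崎県	MIYAZAKI
宮崎市	MIYAZAKI
鹿児島	KAGOSHIMA
鹿児島県	KAGOSHIMA
鹿児島市	KAGOSHIMA
沖縄	OKINAWA
沖縄県	OKINAWA
那覇市	OKINAWA
沖縄市	OKINAWA
チェルノブイリ	OTHER
スリーマイル島	OTHER
丁目	OTHER
番地	OTHER
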