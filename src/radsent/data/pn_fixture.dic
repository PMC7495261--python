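カカク:カカク:名詞:-1.00
キカセ:キカセ:名詞:-0.95
クカテ:クカテ:名詞:-0.90
ケカネ:ケカネ:名詞:-0.85
コカヘ:コカヘ:名詞:-0.80
サカメ:サカメ:名詞:-0.75
スカラ:スカラ:名詞:-0.70
セカカ:セカカ:名詞:-0.65
ソカサ:ソカサ:名詞:-0.60
タカチ:タカチ:名詞:-0.55
チカニ:チカニ:名詞:-0.50
ツカヒ:ツカヒ:名詞:-0.45
テカミ:テカミ:名詞:-0.40
トカユ:トカユ:名詞:-0.35
ナカレ:ナカレ:名詞:-0.30
ニカケ:ニカケ:名詞:-0.25
ヌカソ:ヌカソ:名詞:-0.20
ネカト:ネカト:名詞:-0.15
ノカノ:ノカノ:名詞:-0.10
ハカホ:ハカホ:名詞:-0.05
ヒカモ:ヒカモ:名詞:0.00
フカリ:フカリ:名詞:0.05
ヘカキ:ヘカキ:名詞:0.10
ホカス:ホカス:名詞:0.15
マカツ:マカツ:名詞:0.20
ミカヌ:ミカヌ:名詞:0.25
ムカフ:ムカフ:名詞:0.30
メカム:メカム:名詞:0.35
モカヨ:モカヨ:名詞:0.40
ヤカロ:ヤカロ:名詞:0.45
ユカコ:ユカコ:名詞:0.50
ヨカタ:ヨカタ:名詞:0.55
ラカナ:ラカナ:名詞:0.60
リカハ:リカハ:名詞:0.65
ルカマ:ルカマ:名詞:0.70
レカヤ:レカヤ:名詞:0.75
ロカル:ロカル:名詞:0.80
カキク:カキク:名詞:0.85
キキセ:キキセ:名詞:0.90
クキテ:クキテ:名詞:0.95
ケキネ:ケキネ:名詞:1.00
放射能:ほうしゃのう:名詞:-0.598318
放射線:ほうしゃせん:名詞:-0.560393
放射性:ほうしゃせい:名詞:-0.178744
優れる:すぐれる:動詞:1
良い:よい:形容詞:0.999995
悪い:わるい:形容詞:-0.999999
安全:あんぜん:名詞:0.686485
危険:きけん:名詞:-0.941294
嬉しい:うれしい:形容詞:0.98
怖い:こわい:形容詞:-0.95
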