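# WAG amino-acid substitution model (Whelan & Goldman 2001).
# 'pair X Y value' = symmetric exchangeability; 'freq X value' = stationary frequency.
pair A R 0.551571
pair A N 0.509848
pair A D 0.738998
pair A C 1.02704
pair A Q 0.908598
pair A E 1.58285
pair A G 1.41672
pair A H 0.316954
pair A I 0.193335
pair A L 0.397915
pair A K 0.906265
pair A M 0.893496
pair A F 0.210494
pair A P 1.43855
pair A S 3.37079
pair A T 2.12111
pair A W 0.113133
pair A Y 0.240735
pair A V 2.00601
pair R N 0.635346
pair R D 0.147304
pair R C 0.528191
pair R Q 3.0355
pair R E 0.439157
pair R G 0.584665
pair R H 2.13715
pair R I 0.186979
pair R L 0.497671
pair R K 5.35142
pair R M 0.683162
pair R F 0.102711
pair R P 0.679489
pair R S 1.22419
pair R T 0.554413
pair R W 1.16392
pair R Y 0.381533
pair R V 0.251849
pair N D 5.42942
pair N C 0.265256
pair N Q 1.54364
pair N E 0.947198
pair N G 1.12556
pair N H 3.95629
pair N I 0.554236
pair N L 0.131528
pair N K 3.01201
pair N M 0.198221
pair N F 0.0961621
pair N P 0.195081
pair N S 3.97423
pair N T 2.03006
pair N W 0.0719167
pair N Y 1.086
pair N V 0.196246
pair D C 0.0302949
pair D Q 0.616783
pair D E 6.17416
pair D G 0.865584
pair D H 0.930676
pair D I 0.039437
pair D L 0.0848047
pair D K 0.479855
pair D M 0.103754
pair D F 0.0467304
pair D P 0.423984
pair D S 1.07176
pair D T 0.374866
pair D W 0.129767
pair D Y 0.325711
pair D V 0.152335
pair C Q 0.0988179
pair C E 0.021352
pair C G 0.306674
pair C H 0.248972
pair C I 0.170135
pair C L 0.384287
pair C K 0.0740339
pair C M 0.390482
pair C F 0.39802
pair C P 0.109404
pair C S 1.40766
pair C T 0.512984
pair C W 0.71707
pair C Y 0.543833
pair C V 1.00214
pair Q E 5.46947
pair Q G 0.330052
pair Q H 4.29411
pair Q I 0.113917
pair Q L 0.869489
pair Q K 3.8949
pair Q M 1.54526
pair Q F 0.0999208
pair Q P 0.933372
pair Q S 1.02887
pair Q T 0.857928
pair Q W 0.215737
pair Q Y 0.22771
pair Q V 0.301281
pair E G 0.567717
pair E H 0.570025
pair E I 0.127395
pair E L 0.154263
pair E K 2.58443
pair E M 0.315124
pair E F 0.0811339
pair E P 0.682355
pair E S 0.704939
pair E T 0.822765
pair E W 0.156557
pair E Y 0.196303
pair E V 0.588731
pair G H 0.24941
pair G I 0.0304501
pair G L 0.0613037
pair G K 0.373558
pair G M 0.1741
pair G F 0.049931
pair G P 0.24357
pair G S 1.34182
pair G T 0.225833
pair G W 0.336983
pair G Y 0.103604
pair G V 0.187247
pair H I 0.13819
pair H L 0.499462
pair H K 0.890432
pair H M 0.404141
pair H F 0.679371
pair H P 0.696198
pair H S 0.740169
pair H T 0.473307
pair H W 0.262569
pair H Y 3.87344
pair H V 0.118358
pair I L 3.17097
pair I K 0.323832
pair I M 4.25746
pair I F 1.05947
pair I P 0.0999288
pair I S 0.31944
pair I T 1.45816
pair I W 0.212483
pair I Y 0.42017
pair I V 7.8213
pair L K 0.257555
pair L M 4.85402
pair L F 2.11517
pair L P 0.415844
pair L S 0.344739
pair L T 0.326622
pair L W 0.665309
pair L Y 0.398618
pair L V 1.80034
pair K M 0.934276
pair K F 0.088836
pair K P 0.556896
pair K S 0.96713
pair K T 1.38698
pair K W 0.137505
pair K Y 0.133264
pair K V 0.305434
pair M F 1.19063
pair M P 0.171329
pair M S 0.493905
pair M T 1.51612
pair M W 0.515706
pair M Y 0.428437
pair M V 2.05845
pair F P 0.161444
pair F S 0.545931
pair F T 0.171903
pair F W 1.52964
pair F Y 6.45428
pair F V 0.649892
pair P S 1.61328
pair P T 0.795384
pair P W 0.139405
pair P Y 0.216046
pair P V 0.314887
pair S T 4.37802
pair S W 0.523742
pair S Y 0.786993
pair S V 0.232739
pair T W 0.110864
pair T Y 0.291148
pair T V 1.38823
pair W Y 2.48539
pair W V 0.365369
pair Y V 0.31473
freq A 0.08662791
freq R 0.043972
freq N 0.0390894
freq D 0.05704511
freq C 0.0193078
freq Q 0.0367281
freq E 0.05805891
freq G 0.08325181
freq H 0.0244313
freq I 0.048466
freq L 0.08620901
freq K 0.06202861
freq M 0.0195027
freq F 0.0384319
freq P 0.0457631
freq S 0.06951791
freq T 0.06101271
freq W 0.0143859
freq Y 0.0352742
freq V 0.07089561
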