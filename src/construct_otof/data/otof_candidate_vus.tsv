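variant	rs_id	allele_frequency	mean_rank_score
Leu1504Pro	rs775737412	-	0.925
Asp1608Tyr	rs111033425	0.0000263	0.919
Leu1537His	rs1171483566	-	0.911
Asp1608Ala	-	-	0.905
Gly1602Ser	rs776265576	-	0.904
Trp1606Gly	rs1218385801	-	0.892
Pro1128Leu	rs1465110068	-	0.889
Pro476Ser	rs573354216	0.0000066	0.873
Pro1628Thr	rs760176622	-	0.857
Gly562Ser	rs1415917697	0.0000131	0.849
Arg1127Gln	rs1408254984	0.0000132	0.846
Gly511Ser	rs1484959545	0.0000066	0.844
Glu1687Lys	rs1407487182	-	0.843
Val1498Gly	rs752201516	-	0.832
Ser542Phe	rs1467064287	-	0.822
Val456Met	rs753282692	0.0000131	0.799
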