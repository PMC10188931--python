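subject_id,metric,value_mdi1,value_mdi2
1,cmax,18.3,14.2
2,cmax,11.3,19.3
3,cmax,16.5,22.3
4,cmax,13.6,11.6
5,cmax,15.2,15.6
6,cmax,36.3,17.3
7,cmax,16.2,16.1
8,cmax,21.3,17.2
1,auc,701,483
2,auc,391,853
3,auc,754,952
4,auc,670,321
5,auc,649,686
6,auc,1630,778
7,auc,753,544
8,auc,1030,776
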