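dataset_id,week,parameter,p10,p50,p90
intergrowth21,38,BPD,8.865117,9.332471,9.799825
intergrowth21,38,HC,31.188062,32.685116,34.182170
intergrowth21,38,AC,30.751497,33.236276,35.721055
intergrowth21,38,FL,6.554399,6.934102,7.313805
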