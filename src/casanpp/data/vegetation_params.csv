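class_code,class_name,sr_max,e_max
1,needleleaved_deciduous_forest,6.63,0.485
2,needleleaved_evergreen_forest,4.67,0.389
3,broadleaved_evergreen_forest,5.17,0.985
4,broadleaved_deciduous_forest,6.91,0.692
5,bush,4.49,0.429
6,sparse_woods,4.49,0.542
7,alpine_subalpine_grassland,4.46,0.542
8,lake,4.46,0.542
9,rock,4.46,0.542
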