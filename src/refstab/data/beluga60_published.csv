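# Published stability values and ranks, 13 candidate housekeeping genes, 60 beluga blood samples
gene,geomean,rank,delta_ct_value,delta_ct_rank,bestkeeper_value,bestkeeper_rank,normfinder_value,normfinder_rank,genorm_value,genorm_rank
RPL4,2.3,1,0.562,2,0.523,7,0.319,2,0.336,1
PGK1,2.38,2,0.556,1,0.595,8,0.296,1,0.386,4
B2M,3.08,3,0.614,5,0.474,3,0.418,6,0.336,1
ACTB,3.57,4,0.569,3,0.522,6,0.326,3,0.345,3
RPL18,4.6,5,0.587,4,0.509,4,0.34,4,0.478,7
RPL8,4.82,6,0.664,9,0.423,1,0.499,10,0.46,6
RPS18,4.86,7,0.634,7,0.45,2,0.466,8,0.435,5
RPS9,6.82,8,0.629,6,0.712,9,0.416,5,0.507,8
YWHAZ,8.43,9,0.649,8,0.728,10,0.454,7,0.541,9
LDHB,9.64,10,0.74,12,0.519,5,0.594,12,0.6,12
HPRT1,10.19,11,0.674,10,0.761,12,0.493,9,0.564,10
GAPDH,11,12,0.684,11,0.759,11,0.511,11,0.58,11
TFRC,13,13,0.956,13,0.88,13,0.857,13,0.655,13
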