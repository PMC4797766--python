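# Published stability values and ranks, 13 candidate housekeeping genes, 30 beluga blood samples
gene,geomean,rank,delta_ct_value,delta_ct_rank,bestkeeper_value,bestkeeper_rank,normfinder_value,normfinder_rank,genorm_value,genorm_rank
PGK1,2.21,1,0.552,1,0.647,8,0.26,1,0.343,3
ACTB,2.45,2,0.593,3,0.561,6,0.356,2,0.331,1
RPL4,2.74,3,0.591,2,0.564,7,0.362,4,0.331,1
RPL8,4.43,4,0.678,8,0.402,1,0.51,8,0.432,6
RPL18,4.53,5,0.616,4,0.557,5,0.359,3,0.469,7
B2M,4.56,6,0.637,6,0.491,3,0.451,6,0.364,4
RPS18,4.7,7,0.642,7,0.431,2,0.473,7,0.403,5
RPS9,6.71,8,0.625,5,0.788,9,0.372,5,0.522,9
LDHB,7.52,9,0.705,10,0.497,4,0.529,10,0.493,8
YWHAZ,9.72,10,0.703,9,0.92,11,0.513,9,0.563,10
GAPDH,10.74,11,0.732,11,0.87,10,0.558,11,0.595,11
HPRT1,12,12,0.738,12,0.951,12,0.565,12,0.617,12
TFRC,13,13,1.023,13,0.975,13,0.926,13,0.68,13
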