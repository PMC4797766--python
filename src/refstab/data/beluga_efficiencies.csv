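# Published qPCR amplification efficiencies for 13 candidate housekeeping genes in beluga whale blood
gene,efficiency_percent,efficiency_sd,r2
ACTB,97.69,1.15,0.999
B2M,95.81,0.61,0.999
GAPDH,97.03,1.32,1.000
HPRT1,98.17,1.44,0.999
LDHB,100.49,1.58,0.995
PGK1,95.47,0.31,0.999
RPL4,96.91,0.98,0.999
RPL8,101.39,2.47,0.997
RPL18,96.55,0.39,1.000
RPS9,98.96,1.39,0.999
RPS18,98.46,1.23,0.999
TFRC,97.79,2.49,0.996
YWHAZ,98.35,0.66,0.992
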