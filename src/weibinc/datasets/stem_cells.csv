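# Stem cell number and division rate per tissue (literature estimates).
cancer,stem_cells,division_rate
AML,1.35e+08,12.000
BCC,5.82e+09,7.600
CLL,1.35e+08,12.000
COAD,2.00e+08,73.000
DUAD,4.00e+06,24.000
ESCA,8.64e+05,17.400
GBNPAD,1.60e+06,0.584
GBM,1.35e+08,0.000
HNSC,1.85e+07,21.500
LHCA,3.01e+09,0.912
LUAD,1.22e+09,0.070
MBM,1.36e+08,0.000
SKCM,3.80e+09,2.480
OSARC,4.18e+06,0.067
OSARCA,6.50e+05,0.067
OSARCH,8.60e+05,0.067
OSARCL,1.59e+06,0.067
OSARCP,4.50e+05,0.067
OVGC,1.10e+07,0.000
PDAD,4.18e+09,1.000
PECA,7.40e+07,1.000
SIAD,1.00e+08,36.000
TGCC,7.20e+06,5.800
TPFC,6.50e+07,0.087
TMCA,6.50e+06,0.087
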