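# 6-31G split-valence basis, plain-text exchange format.
# Standard published Pople parameters for H, He, C, N, O.
# 6-31G* adds a 6-component Cartesian d shell (exponent 0.8) on C/N/O and
# 6-31G** additionally a p shell (exponent 1.1) on H/He; those
# polarization shells are appended programmatically by the basis builder.
# (P is not shipped for this basis; phosphorus systems use STO-3G.)

element H
shell S
  18.73113696  0.03349460
  2.82539437   0.23472695
  0.64012169   0.81375733
shell S
  0.16127776   1.00000000

element He
shell S
  38.42163400  0.02376600
  5.77803000   0.15467900
  1.24177400   0.46963000
shell S
  0.29796400   1.00000000

element C
shell S
  3047.52488000 0.00183474
  457.36951800  0.01403732
  103.94868500  0.06884262
  29.21015530   0.23218444
  9.28666296    0.46794135
  3.16392696    0.36231199
shell SP
  7.86827235   -0.11933242  0.06899907
  1.88128854   -0.16085415  0.31642396
  0.54424926    1.14345644  0.74430829
shell SP
  0.16871448    1.00000000  1.00000000

element N
shell S
  4173.51146000 0.00183477
  627.45791100  0.01399463
  142.90209300  0.06858655
  40.23432930   0.23224102
  12.82021290   0.46907003
  4.39043701    0.36045520
shell SP
  11.62636186  -0.11496118  0.06757974
  2.71627981   -0.16911748  0.32390730
  0.77221840    1.14585195  0.74089514
shell SP
  0.21203150    1.00000000  1.00000000

element O
shell S
  5484.67166000 0.00183107
  825.23494600  0.01395017
  188.04695800  0.06844508
  52.96450000   0.23271434
  16.89757040   0.47019290
  5.79963534    0.35852085
shell SP
  15.53961625  -0.11077755  0.07087427
  3.59993359   -0.14802626  0.33975284
  1.01376175    1.13076701  0.72715858
shell SP
  0.27000582    1.00000000  1.00000000
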