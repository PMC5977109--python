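# 3-21G split-valence basis, plain-text exchange format.
# Standard published Pople split-valence parameters for H, He, C, N, O.
# (P is not shipped for this basis; phosphorus systems use STO-3G.)

element H
shell S
  5.44717800   0.15628500
  0.82454700   0.90469100
shell S
  0.18319200   1.00000000

element He
shell S
  13.62670000  0.17523000
  1.99935000   0.89348300
shell S
  0.38299300   1.00000000

element C
shell S
  172.25600000 0.06176690
  25.91090000  0.35879400
  5.53335000   0.70071300
shell SP
  3.66498000  -0.39589700  0.23646000
  0.77054500   1.21584000  0.86061900
shell SP
  0.19585700   1.00000000  1.00000000

element N
shell S
  242.76600000 0.05986570
  36.48510000  0.35295500
  7.81449000   0.70651300
shell SP
  5.42552000  -0.41330100  0.23797200
  1.14915000   1.22442000  0.85895300
shell SP
  0.28320500   1.00000000  1.00000000

element O
shell S
  322.03700000 0.05923940
  48.43080000  0.35150000
  10.42060000  0.70765800
shell SP
  7.40294000  -0.40445300  0.24458600
  1.57620000   1.22156000  0.85395500
shell SP
  0.37368400   1.00000000  1.00000000
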