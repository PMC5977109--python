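# STO-3G minimal basis (s/p), plain-text exchange format.
# Each contracted shell: "shell S" rows are "exponent  c_s";
# "shell SP" rows are "exponent  c_s  c_p" (shared exponents).
#
# Provenance: universal STO->3G least-squares expansions of Slater
# functions (zeta = 1) scaled by the standard per-element Slater zetas
# (exponents scale as zeta^2). 1s/2sp universal expansions are the
# published values; the 3sp expansion (needed for P) was recomputed from
# the same least-squares criterion and reproduces the published 3s/3p
# contraction coefficients. Zetas: H 1.24; He 1.69; C 5.67/1.72;
# N 6.67/1.95; O 7.66/2.25; P 14.50/5.31/1.90.

element H
shell S
  3.42525091   0.15432897
  0.62391373   0.53532814
  0.16885540   0.44463454

element He
shell S
  6.36242139   0.15432897
  1.15892300   0.53532814
  0.31364979   0.44463454

element C
shell S
  71.61683700  0.15432897
  13.04509630  0.53532814
  3.53051216   0.44463454
shell SP
  2.94124940  -0.09996723  0.15591627
  0.68348310   0.39951283  0.60768372
  0.22228990   0.70011547  0.39195739

element N
shell S
  99.10616900  0.15432897
  18.05231200  0.53532814
  4.88566020   0.44463454
shell SP
  3.78045590  -0.09996723  0.15591627
  0.87849660   0.39951283  0.60768372
  0.28571440   0.70011547  0.39195739

element O
shell S
  130.70932000 0.15432897
  23.80886100  0.53532814
  6.44360830   0.44463454
shell SP
  5.03315130  -0.09996723  0.15591627
  1.16959610   0.39951283  0.60768372
  0.38038900   0.70011547  0.39195739

element P
shell S
  468.36563700 0.15432897
  85.31336550  0.53532814
  23.08913480  0.44463454
shell SP
  28.03236140 -0.09996723  0.15591627
  6.51394160   0.39951283  0.60768372
  2.11861550   0.70011547  0.39195739
shell SP
  1.74310380  -0.21958595  0.01058605
  0.48634216   0.22555963  0.59508366
  0.19034297   0.90025817  0.46193690
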