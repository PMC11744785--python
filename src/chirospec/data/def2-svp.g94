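! def2-SVP split-valence polarized basis (Weigend, Ahlrichs), Gaussian94 format
****
H     0
S   3   1.00
     13.0107010            0.019682158
      1.9622572            0.13796524
      0.44453796           0.47831935
S   1   1.00
      0.12194962           1.0
P   1   1.00
      0.8                  1.0
****
He    0
S   3   1.00
     38.354936737          0.023814288905
      5.7689081479         0.15490906777
      1.2399407035         0.46998096633
S   1   1.00
      0.29757815953        1.0
P   1   1.00
      1.0                  1.0
****
C     0
S   5   1.00
   1238.4016938            0.0054568832082
    186.29004992           0.040638409211
     42.251176346          0.18025593888
     11.676557932          0.46315121755
      3.5930506482         0.44087173314
S   1   1.00
      0.40245147363        1.0
S   1   1.00
      0.13090182668        1.0
P   3   1.00
      9.4680970621         0.038387871728
      2.0103545142         0.21117025112
      0.54771004707        0.51328172114
P   1   1.00
      0.15268613795        1.0
D   1   1.00
      0.8                  1.0
****
N     0
S   5   1.00
   1712.8415853           -0.0053934125305
    257.64812677          -0.040221581118
     58.458245853         -0.17931144990
     16.198367905         -0.46376317823
      5.0052600809        -0.44171422662
S   1   1.00
      0.58731856571        1.0
S   1   1.00
      0.18764592253        1.0
P   3   1.00
     13.571470233         -0.040072398852
      2.9257372874        -0.21807045028
      0.79927750754       -0.51294466049
P   1   1.00
      0.21954348034        1.0
D   1   1.00
      1.0                  1.0
****
O     0
S   5   1.00
   2266.1767785           -0.0053431809926
    340.87010191          -0.039890039230
     77.363135167         -0.17853911985
     21.479644940         -0.46427684959
      6.6589433124        -0.44309745172
S   1   1.00
      0.80975975668        1.0
S   1   1.00
      0.25530772234        1.0
P   3   1.00
     17.721504317          0.043394573193
      3.8635505440         0.23094120765
      1.0480920883         0.51375311064
P   1   1.00
      0.27641544411        1.0
D   1   1.00
      1.2                  1.0
****
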