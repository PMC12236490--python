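# SYNTHETIC stand-in contact-energy table for residue pairs (kJ/mol).
# Generated from a hydrophobicity sum-product rule; preserves the
# qualitative structure of knowledge-based contact potentials
# (symmetric, uniformly attractive, hydrophobic pairs strongest).
res_i,res_j,eps
A,A,2.3746
A,C,3.1846
A,D,1.6635
A,E,1.7491
A,F,3.3492
A,G,2.1705
A,H,2.2561
A,I,3.3558
A,K,1.5186
A,L,3.2900
A,M,2.9805
A,N,1.7754
A,P,2.6446
A,Q,2.0256
A,R,1.5054
A,S,2.1442
A,T,2.3417
A,V,2.9739
A,W,3.6521
A,Y,2.8027
C,C,4.5241
C,D,2.0085
C,E,2.1500
C,F,4.7963
C,G,2.8470
C,H,2.9886
C,I,4.8072
C,K,1.7689
C,L,4.6983
C,M,4.1865
C,N,2.1936
C,P,3.6311
C,Q,2.6074
C,R,1.7471
C,S,2.8034
C,T,3.1301
C,V,4.1756
C,W,5.2973
C,Y,3.8924
D,D,1.3605
D,E,1.3970
D,F,2.0786
D,G,1.5765
D,H,1.6130
D,I,2.0814
D,K,1.2988
D,L,2.0534
D,M,1.9215
D,N,1.4082
D,P,1.7785
D,Q,1.5148
D,R,1.2932
D,S,1.5653
D,T,1.6494
D,V,1.9187
D,W,2.2076
D,Y,1.8458
E,E,1.4394
E,F,2.2315
E,G,1.6480
E,H,1.6904
E,I,2.2348
E,K,1.3253
E,L,2.2022
E,M,2.0490
E,N,1.4524
E,P,1.8827
E,Q,1.5763
E,R,1.3187
E,S,1.6350
E,T,1.7328
E,V,2.0457
E,W,2.3815
E,Y,1.9610
F,F,5.0904
F,G,2.9845
F,H,3.1374
F,I,5.1022
F,K,1.8198
F,L,4.9846
F,M,4.4316
F,N,2.2786
F,P,3.8316
F,Q,2.7257
F,R,1.7962
F,S,2.9374
F,T,3.2904
F,V,4.4198
F,W,5.6316
F,Y,4.1139
G,G,2.0000
G,H,2.0715
G,I,2.9900
G,K,1.4555
G,L,2.9350
G,M,2.6765
G,N,1.6700
G,P,2.3960
G,Q,1.8790
G,R,1.4445
G,S,1.9780
G,T,2.1430
G,V,2.6710
G,W,3.2375
G,Y,2.5280
H,H,2.1489
H,I,3.1434
H,K,1.4820
H,L,3.0838
H,M,2.8040
H,N,1.7142
H,P,2.5003
H,Q,1.9405
H,R,1.4700
H,S,2.0477
H,T,2.2263
H,V,2.7980
H,W,3.4114
H,Y,2.6432
I,I,5.1140
I,K,1.8218
I,L,4.9960
I,M,4.4414
I,N,2.2820
I,P,3.8396
I,Q,2.7304
I,R,1.7982
I,S,2.9428
I,T,3.2968
I,V,4.4296
I,W,5.6450
I,Y,4.1228
K,K,1.2540
K,L,1.8014
K,M,1.7058
K,N,1.3334
K,P,1.6020
K,Q,1.4107
K,R,1.2500
K,S,1.4474
K,T,1.5084
K,V,1.7038
K,W,1.9134
K,Y,1.6509
L,L,4.8815
L,M,4.3434
L,N,2.2480
L,P,3.7594
L,Q,2.6831
L,R,1.7786
L,S,2.8892
L,T,3.2327
L,V,4.3319
L,W,5.5113
L,Y,4.0342
M,M,3.8825
M,N,2.0882
M,P,3.3825
M,Q,2.4608
M,R,1.6862
M,S,2.6373
M,T,2.9314
M,V,3.8727
M,W,4.8826
M,Y,3.6178
N,N,1.4660
N,P,1.9148
N,Q,1.5952
N,R,1.3266
N,S,1.6564
N,T,1.7584
N,V,2.0848
N,W,2.4350
N,Y,1.9964
P,P,2.9734
P,Q,2.2196
P,R,1.5860
P,S,2.3639
P,T,2.6045
P,V,3.3744
P,W,4.2005
P,Y,3.1659
Q,Q,1.7749
Q,R,1.4013
Q,S,1.8601
Q,T,2.0020
Q,V,2.4561
Q,W,2.9433
Q,Y,2.3331
R,R,1.2460
R,S,1.4366
R,T,1.4956
R,V,1.6842
R,W,1.8866
R,Y,1.6331
S,S,1.9566
S,T,2.1174
S,V,2.6319
S,W,3.1840
S,Y,2.4926
T,T,2.3097
T,V,2.9250
T,W,3.5853
T,Y,2.7584
V,V,3.8629
V,W,4.8693
V,Y,3.6089
W,W,6.2469
W,Y,4.5215
Y,Y,3.3786
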