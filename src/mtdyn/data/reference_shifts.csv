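residue_type,atom_name,source,mean_ppm,sd_ppm
A,CA,bmrb_average,53.2,2.0
A,CA,random_coil,52.5,0.4
A,CB,bmrb_average,19.0,1.9
A,CB,random_coil,19.1,0.4
A,H,bmrb_average,8.2,0.6
A,HA,bmrb_average,4.26,0.44
A,HA,random_coil,4.32,0.4
A,HB,bmrb_average,1.35,0.26
A,N,bmrb_average,123.2,3.5
C,CA,bmrb_average,58.2,3.3
C,CA,random_coil,58.2,0.4
C,CB,bmrb_average,32.8,6.1
C,CB,random_coil,28.0,0.4
C,H,bmrb_average,8.38,0.67
C,HA,bmrb_average,4.69,0.57
C,HA,random_coil,4.71,0.4
C,HB,bmrb_average,2.95,0.45
C,N,bmrb_average,120.1,4.5
D,CA,bmrb_average,54.7,2.0
D,CA,random_coil,54.2,0.4
D,CB,bmrb_average,40.9,1.6
D,CB,random_coil,41.1,0.4
D,H,bmrb_average,8.31,0.58
D,HA,bmrb_average,4.59,0.32
D,HA,random_coil,4.64,0.4
D,HB,bmrb_average,2.72,0.27
D,N,bmrb_average,120.6,3.9
E,CA,bmrb_average,57.3,2.1
E,CA,random_coil,56.6,0.4
E,CB,bmrb_average,30.0,1.7
E,CB,random_coil,29.9,0.4
E,CG,bmrb_average,36.1,1.2
E,H,bmrb_average,8.33,0.6
E,HA,bmrb_average,4.25,0.41
E,HA,random_coil,4.35,0.4
E,HB,bmrb_average,2.03,0.22
E,HG,bmrb_average,2.28,0.21
E,N,bmrb_average,120.7,3.5
F,CA,bmrb_average,58.1,2.6
F,CA,random_coil,57.7,0.4
F,CB,bmrb_average,39.9,2.1
F,CB,random_coil,39.6,0.4
F,H,bmrb_average,8.36,0.72
F,HA,bmrb_average,4.62,0.57
F,HA,random_coil,4.62,0.4
F,HB,bmrb_average,2.99,0.37
F,N,bmrb_average,120.4,4.1
G,CA,bmrb_average,45.4,1.3
G,CA,random_coil,45.1,0.4
G,H,bmrb_average,8.33,0.64
G,HA,bmrb_average,3.96,0.37
G,HA,random_coil,3.96,0.4
G,N,bmrb_average,109.7,3.8
H,CA,bmrb_average,56.5,2.3
H,CA,random_coil,55.0,0.4
H,CB,bmrb_average,30.2,2.1
H,CB,random_coil,29.0,0.4
H,H,bmrb_average,8.25,0.68
H,HA,bmrb_average,4.61,0.44
H,HA,random_coil,4.73,0.4
H,HB,bmrb_average,3.1,0.36
H,N,bmrb_average,119.6,4.0
I,CA,bmrb_average,61.6,2.7
I,CA,random_coil,61.3,0.4
I,CB,bmrb_average,38.6,2.0
I,CB,random_coil,38.0,0.4
I,CD1,bmrb_average,13.4,1.7
I,CG1,bmrb_average,27.7,1.7
I,CG2,bmrb_average,17.5,1.4
I,H,bmrb_average,8.26,0.69
I,HA,bmrb_average,4.17,0.57
I,HA,random_coil,4.17,0.4
I,HB,bmrb_average,1.79,0.3
I,HD1,bmrb_average,0.68,0.29
I,HG1,bmrb_average,1.27,0.41
I,HG2,bmrb_average,0.78,0.27
I,N,bmrb_average,121.5,4.3
K,CA,bmrb_average,56.9,2.2
K,CA,random_coil,56.2,0.4
K,CB,bmrb_average,32.8,1.8
K,CB,random_coil,33.1,0.4
K,CD,bmrb_average,28.9,1.1
K,CE,bmrb_average,41.9,0.8
K,CG,bmrb_average,24.9,1.1
K,H,bmrb_average,8.18,0.6
K,HA,bmrb_average,4.25,0.44
K,HA,random_coil,4.32,0.4
K,HB,bmrb_average,1.78,0.25
K,HD,bmrb_average,1.61,0.22
K,HE,bmrb_average,2.92,0.19
K,HG,bmrb_average,1.37,0.26
K,N,bmrb_average,121.0,3.8
L,CA,bmrb_average,55.6,2.1
L,CA,random_coil,55.1,0.4
L,CB,bmrb_average,42.3,1.9
L,CB,random_coil,42.4,0.4
L,CD,bmrb_average,24.6,1.6
L,CG,bmrb_average,26.8,1.1
L,H,bmrb_average,8.22,0.65
L,HA,bmrb_average,4.32,0.47
L,HA,random_coil,4.34,0.4
L,HB,bmrb_average,1.62,0.34
L,HD,bmrb_average,0.75,0.28
L,HG,bmrb_average,1.51,0.33
L,N,bmrb_average,121.8,3.9
M,CA,bmrb_average,56.1,2.2
M,CA,random_coil,55.4,0.4
M,CB,bmrb_average,33.0,2.2
M,CB,random_coil,32.9,0.4
M,CE,bmrb_average,17.1,1.5
M,CG,bmrb_average,32.0,1.3
M,H,bmrb_average,8.25,0.6
M,HA,bmrb_average,4.41,0.48
M,HA,random_coil,4.48,0.4
M,HB,bmrb_average,2.03,0.34
M,HE,bmrb_average,1.86,0.4
M,HG,bmrb_average,2.43,0.36
M,N,bmrb_average,120.1,3.6
N,CA,bmrb_average,53.5,1.9
N,CA,random_coil,52.8,0.4
N,CB,bmrb_average,38.7,1.8
N,CB,random_coil,37.9,0.4
N,H,bmrb_average,8.33,0.63
N,HA,bmrb_average,4.67,0.37
N,HA,random_coil,4.74,0.4
N,HB,bmrb_average,2.81,0.33
N,N,bmrb_average,118.9,4.0
P,CA,bmrb_average,63.3,1.5
P,CA,random_coil,63.3,0.4
P,CB,bmrb_average,31.8,1.2
P,CB,random_coil,31.7,0.4
P,CD,bmrb_average,50.3,1.0
P,CG,bmrb_average,27.2,1.1
P,HA,bmrb_average,4.4,0.33
P,HA,random_coil,4.42,0.4
P,HB,bmrb_average,2.07,0.35
P,HD,bmrb_average,3.65,0.35
P,HG,bmrb_average,1.93,0.31
Q,CA,bmrb_average,56.6,2.2
Q,CA,random_coil,55.7,0.4
Q,CB,bmrb_average,29.2,1.9
Q,CB,random_coil,29.4,0.4
Q,CG,bmrb_average,33.8,1.1
Q,H,bmrb_average,8.22,0.59
Q,HA,bmrb_average,4.27,0.44
Q,HA,random_coil,4.34,0.4
Q,HB,bmrb_average,2.05,0.26
Q,HG,bmrb_average,2.32,0.28
Q,N,bmrb_average,119.9,3.6
R,CA,bmrb_average,56.8,2.3
R,CA,random_coil,56.0,0.4
R,CB,bmrb_average,30.7,1.9
R,CB,random_coil,30.9,0.4
R,CD,bmrb_average,43.2,0.9
R,CG,bmrb_average,27.2,1.2
R,H,bmrb_average,8.23,0.61
R,HA,bmrb_average,4.3,0.46
R,HA,random_coil,4.34,0.4
R,HB,bmrb_average,1.79,0.28
R,HD,bmrb_average,3.12,0.24
R,HG,bmrb_average,1.57,0.28
R,N,bmrb_average,120.8,3.7
S,CA,bmrb_average,58.7,2.1
S,CA,random_coil,58.3,0.4
S,CB,bmrb_average,63.8,1.5
S,CB,random_coil,63.8,0.4
S,H,bmrb_average,8.29,0.59
S,HA,bmrb_average,4.47,0.4
S,HA,random_coil,4.47,0.4
S,HB,bmrb_average,3.87,0.26
S,N,bmrb_average,116.3,3.5
T,CA,bmrb_average,62.2,2.6
T,CA,random_coil,61.8,0.4
T,CB,bmrb_average,69.7,1.6
T,CB,random_coil,69.8,0.4
T,CG2,bmrb_average,21.5,1.2
T,H,bmrb_average,8.24,0.62
T,HA,bmrb_average,4.45,0.48
T,HA,random_coil,4.35,0.4
T,HB,bmrb_average,4.16,0.33
T,HG2,bmrb_average,1.14,0.23
T,N,bmrb_average,115.5,4.7
V,CA,bmrb_average,62.5,2.9
V,CA,random_coil,62.2,0.4
V,CB,bmrb_average,32.7,1.8
V,CB,random_coil,32.9,0.4
V,CG,bmrb_average,21.4,1.5
V,CG1,bmrb_average,21.5,1.4
V,CG2,bmrb_average,21.3,1.6
V,H,bmrb_average,8.28,0.68
V,HA,bmrb_average,4.17,0.58
V,HA,random_coil,4.12,0.4
V,HB,bmrb_average,1.98,0.32
V,HG,bmrb_average,0.81,0.27
V,HG1,bmrb_average,0.82,0.27
V,HG2,bmrb_average,0.8,0.28
V,N,bmrb_average,121.2,4.4
W,CA,bmrb_average,57.7,2.6
W,CA,random_coil,57.5,0.4
W,CB,bmrb_average,29.9,2.0
W,CB,random_coil,29.6,0.4
W,H,bmrb_average,8.28,0.78
W,HA,bmrb_average,4.66,0.52
W,HA,random_coil,4.66,0.4
W,HB,bmrb_average,3.18,0.36
W,N,bmrb_average,121.7,4.1
Y,CA,bmrb_average,58.1,2.5
Y,CA,random_coil,57.9,0.4
Y,CB,bmrb_average,39.2,2.2
Y,CB,random_coil,38.8,0.4
Y,H,bmrb_average,8.32,0.73
Y,HA,bmrb_average,4.62,0.55
Y,HA,random_coil,4.55,0.4
Y,HB,bmrb_average,2.9,0.37
Y,N,bmrb_average,120.4,4.2
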