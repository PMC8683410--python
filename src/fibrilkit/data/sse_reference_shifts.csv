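residue,sse,ca_ppm,cb_ppm
A,helix,55.6,18.6
A,strand,51.0,21.3
A,coil,52.5,19.1
C,helix,61.3,27.5
C,strand,56.7,30.2
C,coil,58.2,28.0
D,helix,57.3,40.6
D,strand,52.7,43.3
D,coil,54.2,41.1
E,helix,59.7,29.4
E,strand,55.1,32.1
E,coil,56.6,29.9
F,helix,60.8,39.1
F,strand,56.2,41.8
F,coil,57.7,39.6
G,helix,48.2,
G,strand,43.6,
G,coil,45.1,
H,helix,58.1,28.5
H,strand,53.5,31.2
H,coil,55.0,29.0
I,helix,64.2,38.3
I,strand,59.6,41.0
I,coil,61.1,38.8
K,helix,59.3,32.6
K,strand,54.7,35.3
K,coil,56.2,33.1
L,helix,58.2,41.9
L,strand,53.6,44.6
L,coil,55.1,42.4
M,helix,58.5,32.4
M,strand,53.9,35.1
M,coil,55.4,32.9
N,helix,56.5,38.4
N,strand,51.9,41.1
N,coil,53.4,38.9
P,helix,66.4,31.6
P,strand,61.8,34.3
P,coil,63.3,32.1
Q,helix,58.8,28.9
Q,strand,54.2,31.6
Q,coil,55.7,29.4
R,helix,59.1,30.4
R,strand,54.5,33.1
R,coil,56.0,30.9
S,helix,61.4,63.3
S,strand,56.8,66.0
S,coil,58.3,63.8
T,helix,64.9,69.3
T,strand,60.3,72.0
T,coil,61.8,69.8
V,helix,65.3,32.4
V,strand,60.7,35.1
V,coil,62.2,32.9
W,helix,60.6,29.1
W,strand,56.0,31.8
W,coil,57.5,29.6
Y,helix,61.0,38.3
Y,strand,56.4,41.0
Y,coil,57.9,38.8
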