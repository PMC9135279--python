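# 60-electrode layout, 200 um pitch, 30 um diameter; corners absent.
# Channel order is package convention (column-major).
label,channel_index,x_um,y_um
A2,1,0,200
A3,2,0,400
A4,3,0,600
A5,4,0,800
A6,5,0,1000
A7,6,0,1200
B1,7,200,0
B2,8,200,200
B3,9,200,400
B4,10,200,600
B5,11,200,800
B6,12,200,1000
B7,13,200,1200
B8,14,200,1400
C1,15,400,0
C2,16,400,200
C3,17,400,400
C4,18,400,600
C5,19,400,800
C6,20,400,1000
C7,21,400,1200
C8,22,400,1400
D1,23,600,0
D2,24,600,200
D3,25,600,400
D4,26,600,600
D5,27,600,800
D6,28,600,1000
D7,29,600,1200
D8,30,600,1400
E1,31,800,0
E2,32,800,200
E3,33,800,400
E4,34,800,600
E5,35,800,800
E6,36,800,1000
E7,37,800,1200
E8,38,800,1400
F1,39,1000,0
F2,40,1000,200
F3,41,1000,400
F4,42,1000,600
F5,43,1000,800
F6,44,1000,1000
F7,45,1000,1200
F8,46,1000,1400
G1,47,1200,0
G2,48,1200,200
G3,49,1200,400
G4,50,1200,600
G5,51,1200,800
G6,52,1200,1000
G7,53,1200,1200
G8,54,1200,1400
H2,55,1400,200
H3,56,1400,400
H4,57,1400,600
H5,58,1400,800
H6,59,1400,1000
H7,60,1400,1200
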