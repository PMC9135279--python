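# 120-electrode layout, 200 um pitch, 30 um diameter.
# Channel order is package convention (column-major, rotated so F7 is channel 1);
# only 'channel 1 = F7' is fixed by the manufacturer schematic. Row letters skip 'I'.
label,channel_index,x_um,y_um
F7,1,1000,1200
F8,2,1000,1400
F9,3,1000,1600
F10,4,1000,1800
F11,5,1000,2000
F12,6,1000,2200
G1,7,1200,0
G2,8,1200,200
G3,9,1200,400
G4,10,1200,600
G5,11,1200,800
G6,12,1200,1000
G7,13,1200,1200
G8,14,1200,1400
G9,15,1200,1600
G10,16,1200,1800
G11,17,1200,2000
G12,18,1200,2200
H1,19,1400,0
H2,20,1400,200
H3,21,1400,400
H4,22,1400,600
H5,23,1400,800
H6,24,1400,1000
H7,25,1400,1200
H8,26,1400,1400
H9,27,1400,1600
H10,28,1400,1800
H11,29,1400,2000
H12,30,1400,2200
J1,31,1600,0
J2,32,1600,200
J3,33,1600,400
J4,34,1600,600
J5,35,1600,800
J6,36,1600,1000
J7,37,1600,1200
J8,38,1600,1400
J9,39,1600,1600
J10,40,1600,1800
J11,41,1600,2000
J12,42,1600,2200
K2,43,1800,200
K3,44,1800,400
K4,45,1800,600
K5,46,1800,800
K6,47,1800,1000
K7,48,1800,1200
K8,49,1800,1400
K9,50,1800,1600
K10,51,1800,1800
K11,52,1800,2000
L3,53,2000,400
L4,54,2000,600
L5,55,2000,800
L6,56,2000,1000
L7,57,2000,1200
L8,58,2000,1400
L9,59,2000,1600
L10,60,2000,1800
M4,61,2200,600
M5,62,2200,800
M6,63,2200,1000
M7,64,2200,1200
M8,65,2200,1400
M9,66,2200,1600
A4,67,0,600
A5,68,0,800
A6,69,0,1000
A7,70,0,1200
A8,71,0,1400
A9,72,0,1600
B3,73,200,400
B4,74,200,600
B5,75,200,800
B6,76,200,1000
B7,77,200,1200
B8,78,200,1400
B9,79,200,1600
B10,80,200,1800
C2,81,400,200
C3,82,400,400
C4,83,400,600
C5,84,400,800
C6,85,400,1000
C7,86,400,1200
C8,87,400,1400
C9,88,400,1600
C10,89,400,1800
C11,90,400,2000
D1,91,600,0
D2,92,600,200
D3,93,600,400
D4,94,600,600
D5,95,600,800
D6,96,600,1000
D7,97,600,1200
D8,98,600,1400
D9,99,600,1600
D10,100,600,1800
D11,101,600,2000
D12,102,600,2200
E1,103,800,0
E2,104,800,200
E3,105,800,400
E4,106,800,600
E5,107,800,800
E6,108,800,1000
E7,109,800,1200
E8,110,800,1400
E9,111,800,1600
E10,112,800,1800
E11,113,800,2000
E12,114,800,2200
F1,115,1000,0
F2,116,1000,200
F3,117,1000,400
F4,118,1000,600
F5,119,1000,800
F6,120,1000,1000
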