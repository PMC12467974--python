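term,coef_x,coef_y,coef_z
1,0.020,0.010,0.030
X,0.750,0.050,0.000
Y,0.120,0.800,0.060
Z,0.030,0.050,0.850
X^2,0.100,0.000,0.000
Y^2,0.000,0.120,0.000
Z^2,0.000,0.000,0.100
XY,0.050,0.000,0.000
XZ,0.000,0.000,0.050
YZ,0.000,0.040,0.000
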