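# 30 L pilot-scale tubular photobioreactor, modeled as 20 one-sidedly
# illuminated glass-tube compartments of equal projection area.
# compartments: measured surface light intensities [umol_ph m^-2 s^-1],
# row-major over 5 height positions (top to bottom) x 4 depth positions.
r_m: 0.020
V_L_m3: 0.030
A_m2: 1.269
compartments:
  - 606
  - 230
  - 210
  - 28
  - 762
  - 323
  - 286
  - 26
  - 735
  - 392
  - 342
  - 29
  - 836
  - 360
  - 298
  - 21
  - 731
  - 320
  - 185
  - 19
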