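# Prototypical mammalian (HeLa-like) parameter fixture, scaled up from the
# yeast calibration.  Units as in yeast.yaml.
#
# Volume note: the tabulated newborn volumes (1500/500 fL) are inconsistent
# with r = 0.6 applied to the tabulated counts; this package always derives
# volumes from counts (giving V_C = 1210, V_N = 302.5 fL at these counts).
#
# t5 note: the same export/import ratio as yeast applies, t5 = 0.9*t4 = 0.09.
# The rounded tabulated 0.05 makes nuclear import overwhelm export so the
# simulated cell never doubles, contradicting the ~20 h cycle it should show.
organism: mammalian

initial_state:      # newborn cell
  A_C: 21600.0
  P_C: 660.0
  RP_C: 60.0
  R_C: 6.0
  P_N: 165.0
  RP_N: 15.0
  R_N: 1.5

parameters:
  s1: 115.0
  s2: 95.0
  s3: 1.5           # 1/h
  n1: 400
  n2: 400
  n3: 80
  t1: 36.0          # 1/h
  t2: 1.0
  t3: 0.15
  t4: 0.1
  t5: 0.09
  d1C: 0.01
  d1N: 0.01
  d2C: 0.01
  d2N: 0.01
  d3C: 0.01
  d3N: 0.01
  r1: 0.6
  r2: 0.6

modes:
  poor:
    t1_bar_const: 15000.0
  quiescent:
    t1_bar_const: 15000.0
    d_quiescent: 0.05
    s3_override: 0.3

horizons:
  quiescent: 2000.0
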