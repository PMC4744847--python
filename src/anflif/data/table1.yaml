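# Reference parameterization of one cat auditory nerve fiber.
# Units: mu, sigma in uV; tau, phi in us; R in Ohm.
# lat/jit sigmoid coefficients: a1, a2 in uV (effective-threshold
# coordinate), a3, a4 in us.
mu: 104.5
sigma: 4.595
tau: 248.4
R: 1.0
phi: 37.81
lat_params:
  a1: 106.0
  a2: 5.14
  a3: 368.0
  a4: 472.0
jit_params:
  a1: 109.0
  a2: 3.24
  a3: 136.0
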