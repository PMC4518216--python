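material,energy_kev,delta,mu_per_mm
water,15,1.024256e-06,1.673000e-01
water,16,9.002250e-07,1.421603e-01
water,17,7.974312e-07,1.219971e-01
water,18,7.112889e-07,1.056133e-01
water,19,6.383867e-07,9.214563e-02
water,20,5.761440e-07,8.096000e-02
nylon12,15,1.038942e-06,8.792050e-02
nylon12,16,9.131330e-07,7.694374e-02
nylon12,17,8.088652e-07,6.788421e-02
nylon12,18,7.214878e-07,6.032188e-02
nylon12,19,6.475403e-07,5.394547e-02
nylon12,20,5.844051e-07,4.852040e-02
air,15,1.109680e-09,1.944386e-04
air,16,9.753046e-10,1.650712e-04
air,17,8.639377e-10,1.415379e-04
air,18,7.706111e-10,1.224315e-04
air,19,6.916288e-10,1.067382e-04
air,20,6.241950e-10,9.371361e-05
polymer_shell,15,1.038022e-06,3.301100e-01
polymer_shell,16,9.123236e-07,2.772674e-01
polymer_shell,17,8.081482e-07,2.353603e-01
polymer_shell,18,7.208483e-07,2.016678e-01
polymer_shell,19,6.469663e-07,1.742484e-01
polymer_shell,20,5.838871e-07,1.516900e-01
gas_core,15,0.000000e+00,0.000000e+00
gas_core,16,0.000000e+00,0.000000e+00
gas_core,17,0.000000e+00,0.000000e+00
gas_core,18,0.000000e+00,0.000000e+00
gas_core,19,0.000000e+00,0.000000e+00
gas_core,20,0.000000e+00,0.000000e+00
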