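# Initial per-parameter sampling ranges (per-hour units).
# Midpoints form the baseline used to pin non-influential parameters.
N1_inf:
- 0.5
- 1.5
N2_inf:
- 0.5
- 1.5
M11_inf:
- 0.5
- 1.5
M12_inf:
- 0.25
- 0.75
M2_inf:
- 0.5
- 1.5
F_inf:
- 0.5
- 1.5
L21_inf:
- 0.5
- 1.5
L22_inf:
- 0.5
- 1.5
Deb_dam_inf:
- 0.5
- 1.5
Deb_H:
- 0.25
- 0.75
N_H:
- 0.15
- 0.45
M1_H:
- 0.15
- 0.45
gamma_n:
- 0.005
- 0.015
gamma_m:
- 0.005
- 0.015
gamma_l:
- 0.005
- 0.015
gamma_f:
- 0.005
- 0.015
omega_m2:
- 0.06
- 0.18
omega_f:
- 0.15
- 0.45
omega_dam:
- 0.15
- 0.45
kdn:
- 0.0025
- 0.0075
kdm1:
- 0.0025
- 0.0075
rho_dam:
- 0.00375
- 0.01125
kdf:
- 0.0625
- 0.1875
kdnp:
- 0.025
- 0.075
kdm1p:
- 0.025
- 0.075
kdm2p:
- 0.025
- 0.075
ddeb:
- 0.005
- 0.015
snr:
- 0.1
- 0.3
dnr:
- 0.025
- 0.075
knd:
- 0.05
- 0.15
knp:
- 0.05
- 0.15
knn:
- 0.005
- 0.015
knm1p:
- 0.025
- 0.075
knm2p:
- 0.025
- 0.075
dn:
- 0.025
- 0.075
smr:
- 0.0025
- 0.0075
dmr_ud:
- 0.0025
- 0.0075
dmr_d:
- 0.001
- 0.003
km1d:
- 0.025
- 0.075
km1p:
- 0.025
- 0.075
km1n:
- 0.01
- 0.03
km1m1:
- 0.005
- 0.015
km1l1:
- 0.005
- 0.015
km2m1:
- 0.01
- 0.03
km2m2:
- 0.005
- 0.015
km2l2:
- 0.01
- 0.03
theta_m1m2:
- 0.05
- 0.15
dm1:
- 0.01
- 0.03
dm2:
- 0.01
- 0.03
slr:
- 0.005
- 0.015
dlr_ud:
- 0.005
- 0.015
dlr_d:
- 0.02
- 0.06
kl1:
- 0.01
- 0.03
kl2:
- 0.01
- 0.03
dl:
- 0.01
- 0.03
sf:
- 0.001
- 0.003
ksttb_ud:
- 0.001
- 0.003
ksttb_d:
- 0.001
- 0.003
kf:
- 0.005
- 0.015
alpha_dam:
- 0.02
- 0.06
alpha_m2:
- 0.13
- 0.39
dfr_ud:
- 0.0015
- 0.0045
dfr_d:
- 0.002
- 0.006
df:
- 0.01
- 0.03
kpg:
- 0.06
- 0.18
P_inf:
- 0.5
- 1.5
kpb:
- 0.01
- 0.03
sb:
- 0.5
- 1.5
mu_b:
- 0.025
- 0.075
kbp:
- 0.5
- 1.5
kpn:
- 0.015
- 0.045
kpm1:
- 0.025
- 0.075
kpm2:
- 0.025
- 0.075
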