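# Representative parameter set selected by the shipped feasibility
# pipeline: 5000 LHS samples over data/initial_ranges.yaml, seed 2026,
# minimum weighted MSE against the accepted-cohort temporal mean.
N1_inf: 0.853314239144088
N2_inf: 1.0
M11_inf: 0.7556095240782325
M12_inf: 0.5
M2_inf: 1.3569494933933601
F_inf: 1.0
L21_inf: 1.0
L22_inf: 1.0
Deb_dam_inf: 1.0
Deb_H: 0.5
N_H: 0.3
M1_H: 0.3
gamma_n: 0.007941675445908306
gamma_m: 0.008377521156535225
gamma_l: 0.01
gamma_f: 0.01
omega_m2: 0.12
omega_f: 0.2335751238769474
omega_dam: 0.3
kdn: 0.005
kdm1: 0.005
rho_dam: 0.0075
kdf: 0.125
kdnp: 0.05333169955820602
kdm1p: 0.06926100857607079
kdm2p: 0.05
ddeb: 0.01
snr: 0.146453392769507
dnr: 0.05
knd: 0.11159454566654134
knp: 0.1
knn: 0.01
knm1p: 0.03640626896853347
knm2p: 0.05
dn: 0.061790263523469814
smr: 0.003778793192315605
dmr_ud: 0.004420614455878801
dmr_d: 0.002
km1d: 0.05269728847226984
km1p: 0.05794826850005937
km1n: 0.022932227635127856
km1m1: 0.01
km1l1: 0.01
km2m1: 0.02377988730866966
km2m2: 0.01
km2l2: 0.02
theta_m1m2: 0.1
dm1: 0.01850891410098371
dm2: 0.02
slr: 0.01
dlr_ud: 0.01
dlr_d: 0.04
kl1: 0.022512648595675547
kl2: 0.02
dl: 0.02
sf: 0.002
ksttb_ud: 0.002
ksttb_d: 0.002
kf: 0.01
alpha_dam: 0.04
alpha_m2: 0.26
dfr_ud: 0.003
dfr_d: 0.004
df: 0.02
kpg: 0.08762512840519295
P_inf: 1.0502004169827506
kpb: 0.018217153015420103
sb: 1.0080244227196422
mu_b: 0.05
kbp: 0.7738309621281807
kpn: 0.03795846839830712
kpm1: 0.05
kpm2: 0.05
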