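# Population PK parameters for brigatinib (apparent, /F), first-line ALK+ NSCLC.
# Typical values are geometric means; omega entries are log-scale variances of
# the inter-individual random effects; parameters without an omega entry carry
# no random effect (their post hoc distributions are degenerate).
cl_typ: 8.45        # L/h
v1_typ: 160.0       # L
q2_typ: 12.6        # L/h
v2_typ: 118.0       # L
q3_typ: 2.67        # L/h
v3_typ: 78.5        # L
n_transit_typ: 2.76 # transit-compartment count (continuous)
mtt_typ: 1.01       # h, mean transit time
ka_typ: 2.0         # 1/h, first-order absorption after the transit chain
alb_exp: 0.75       # albumin power exponent on CL/F
alb_ref: 41.0       # g/L, reference albumin
omega:              # log-scale variances (diagonal)
  cl: 0.2025        # sd 0.45
  v1: 0.2025        # sd 0.45
  v2: 0.3025        # sd 0.55
  n_transit: 0.1225 # sd 0.35
  mtt: 0.2025       # sd 0.45
sigma_prop: 0.30    # proportional residual SD (fraction)
sigma_add: 1.0      # additive residual SD, ng/mL
lloq: 5.0           # ng/mL, lower limit of quantification
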