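# Synthetic baseline parameter set for the SOC toy model.
# Values are representative of microbial-explicit SOC model literature
# ranges (not a transcription of any published table), chosen so the
# model operates in the regime the comparative experiments describe:
# SOC spans roughly 2-370 mg C/g soil over input rates of 1e-3..10
# mg C/g/d, microbial biomass is 2% of SOC, enzyme production can pay
# off (y*v_u = 10 * eps_e*d_e), and the growth-maximisation schemes are
# infeasible at the lowest input rates.
alpha = 0.5        # fraction of reactive SOC [-]
beta = 0.02        # microbial fraction of SOC [-]
eps_e = 1.5        # enzyme production cost factor [-]
d_e = 0.0015       # enzyme decay rate [1/d]
input_rate = 0.1   # SOC input [mg C/g/d]
k_u = 15.0         # half-saturation constant [mg C/g]
ell_s = 0.01       # abiotic SOC loss rate [1/d]
v_u = 0.05         # max decomposition rate [1/d]
y = 0.45           # microbial yield [-]
c0 = 0.5           # competitive advantage of enzyme producers [-]
d_fixed = 0.0      # mortality for full-ODE mode [1/d]
m_e_fixed = 0.08   # conventional fixed enzyme production rate [1/d]
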