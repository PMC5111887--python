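"""Versioned model constants.

Every kinetic constant, conductance and geometric default of the model lives
here, grouped by mechanism, so a run is fully determined by this file plus the
run configuration (which may override any entry).

Sources
-------
The stage-dependent conductance table (leak, spike, Ca and h-current maximal
conductances; synaptic maximal conductances; miniature-PSP conductances and the
release-rate function; the neuromodulator scaling tables) follows the
thalamocortical sleep-model family of Bazhenov, Timofeev & Sejnowski.  Rate
forms that this family inherits from earlier work are taken from their original
publications:

* Fast Na+/K+ spike currents: Traub-type rate functions (Traub & Miles 1991)
  with a voltage shift, as used in Bazhenov et al. (2002) J Neurosci 22:8691.
* Persistent Na+ current: sigmoidal activation after Alzheimer et al. (1993).
* K+ M-current and high-voltage-activated Ca2+ current: Mainen & Sejnowski
  (1996) reduced-neuron formulation (Reuveni et al. 1993 for the HVA current).
* Ca2+-dependent K+ current: first-order Ca-activated scheme as in the
  Bazhenov lineage cortical dendrite.
* Low-threshold (T-type) Ca2+ currents: Huguenard & Prince (1992) for the
  reticular neuron, Destexhe et al. (1996) J Neurophysiol 76:2049 for the
  relay neuron, with Q10 corrections to 36 C.
* Calcium-gated h-current: Destexhe et al. (1996), five-state scheme
  C<->O, P0+4Ca<->P1, O+P1<->OL with conductance g*([O]+k*[OL]).
* Synaptic first-order activation schemes and the GABA-B G-protein cascade:
  Destexhe et al. (1994) J Comput Neurosci 1:195.
* Short-term depression: use-fraction / exponential-recovery form as in
  Timofeev et al. (2000).

All conductance densities are mS/cm^2, synaptic conductances uS, voltages mV,
times ms, calcium mM, capacitance uF/cm^2.
"""

CONSTANTS_VERSION = "1.0"

# ----------------------------------------------------------------------------
# Reversal potentials (mV)
# ----------------------------------------------------------------------------
E_NA = 50.0
E_K = -95.0
E_CL_CX = -55.0     # cortical mixed Cl-/cation leak reversal
E_LEAK_TC = -70.0   # thalamic relay mixed leak
E_LEAK_RE = -77.0   # reticular mixed leak
E_H = -40.0         # h-current
E_AMPA = 0.0
E_GABAA = -90.0     # thalamic GABA-A (printed table value)
E_GABAA_CX = -70.0  # cortical IN->PY GABA-A: lineage chloride reversal
E_GABAB = -95.0     # K+ channel opened by the G-protein cascade
CA_O = 2.0          # extracellular Ca2+ (mM), Nernst numerator
RT_2F = 13.32       # RT/2F at 36 C (mV), for the Ca2+ Nernst potential

# ----------------------------------------------------------------------------
# Geometry / passive
# ----------------------------------------------------------------------------
CM_CX = 0.75        # cortical membrane capacitance (uF/cm^2); see methods note
CM_TH = 1.0         # thalamic membrane capacitance (uF/cm^2)
S_CX_SOMA = 2.0e-6  # cortical somatic area (cm^2)
RHO_PY = 165.0      # dendritic/somatic area ratio, pyramidal cell
RHO_IN = 50.0       # dendritic/somatic area ratio, interneuron
S_TC = 2.9e-4       # relay-cell area (cm^2)
S_RE = 1.43e-4      # reticular-cell area (cm^2)
KAPPA_MOHM = 5.0    # coupling resistance between compartments (MOhm)
G_CS_US = 1.0 / (KAPPA_MOHM)  # coupling conductance, uS (=0.1 uS for 10 MOhm)

# ----------------------------------------------------------------------------
# Cortical conductances (mS/cm^2) -- dendrite (d) and soma (s)
# ----------------------------------------------------------------------------
PY = dict(
    g_kl=0.007, g_cl=0.023,
    g_nap_d=2.0, g_na_d=0.8, g_ca_d=0.012, g_kca_d=0.015, g_km_d=0.012,
    g_na_s=3000.0, g_k_s=200.0, g_nap_s=15.0,
)
IN = dict(
    g_kl=0.034, g_cl=0.006,
    g_nap_d=0.0, g_na_d=0.8, g_ca_d=0.012, g_kca_d=0.015, g_km_d=0.012,
    g_na_s=2500.0, g_k_s=200.0, g_nap_s=0.0,
)

# ----------------------------------------------------------------------------
# Thalamic conductances (mS/cm^2)
# ----------------------------------------------------------------------------
TC = dict(g_leak=0.01, g_kl=0.007, g_na=90.0, g_k=10.0, g_t=2.5, g_h=0.015)
RE = dict(g_leak=0.05, g_kl=0.016, g_na=100.0, g_k=10.0, g_t=2.2)

# Traub-type spike-current voltage shifts (mV): rates evaluated at V - VTR
VTR_TC = -45.0      # relay-cell Na/K (higher threshold: only full
                    # low-threshold Ca spikes reach firing)
VTR_RE = -50.0      # reticular-cell Na/K
VTR_CX = -50.0      # cortical somatic and dendritic Na, somatic K

# Persistent Na+: m_inf = 1/(1+exp(-(V+42)/5)), activation time constant (ms)
NAP_TAU = 0.2

# M-current and KCa
KM_Q = 1.0                       # rate scale
KCA_ALPHA = 4.0e4                # ms^-1 mM^-2 (alpha = KCA_ALPHA * Ca^2)
KCA_BETA = 0.03                  # ms^-1; half-activation Ca ~ 0.9 uM
CX_NK_SLOW = 3.0                 # cortical somatic K rates divided by this

# ----------------------------------------------------------------------------
# Calcium pools:  dCa/dt = -A*I_Ca/D + (CA_INF - Ca)/TAU   (influx only for
# inward I_Ca); A converts uA/cm^2 to mM/ms for a shell of depth D um.
# ----------------------------------------------------------------------------
CA_A = 5.18e-5      # mM cm^2 / (ms uA)
CA_D = 1.0          # shell depth (um)
CA_INF = 2.4e-4     # resting floor (mM)
CA_TAU_TH = 5.0     # thalamic pool decay (ms)
CA_TAU_CX = 300.0   # cortical dendritic pool decay (ms)
CA_D_CX = 0.15      # cortical shell depth (um): stronger spike Ca signal

# ----------------------------------------------------------------------------
# h-current (relay cells): five-state Ca-gated scheme
# ----------------------------------------------------------------------------
IH = dict(
    e_h=E_H,
    k=3.0,            # conductance weight of the Ca-locked open state OL
    cac=0.0014,       # half-binding Ca (mM): k1 = k2 / cac^4
    k2=4.0e-4,        # unbinding rate (ms^-1)
    k3=0.1,           # O + P1 -> OL (ms^-1)
    k4=2.5e-4,        # OL -> O + P1 (ms^-1): ~4 s refractory
    v_half=75.0,      # h_inf = 1/(1+exp((V + v_half + shift)/slope))
    slope=5.5,
)
IH_K1 = IH["k2"] / IH["cac"] ** 4

# ----------------------------------------------------------------------------
# Synaptic kinetics: first-order scheme dO/dt = alpha*T*(1-O) - beta*O with a
# transmitter pulse T = T_MAX for T_DUR ms after each presynaptic spike.
# ----------------------------------------------------------------------------
T_MAX = 0.5         # transmitter pulse concentration (mM)
T_DUR = 1.0         # transmitter pulse duration, evoked release (ms)
MINI_T_DUR = 0.10   # transmitter pulse duration, single-vesicle minis (ms)
AMPA_ALPHA, AMPA_BETA = 1.1, 0.19      # mM^-1 ms^-1, ms^-1
NMDA_ALPHA, NMDA_BETA = 1.0, 0.0067
GABAA_ALPHA, GABAA_BETA = 10.5, 0.166
NMDA_MG_V0, NMDA_MG_SLOPE = -25.0, 12.5  # Mg-block sigmoid 1/(1+exp(-(V-V0)/s))

# GABA-B G-protein cascade (Destexhe et al. 1994):
# dR/dt = K1*T*(1-R) - K2*R ; dG/dt = K3*R - K4*G ; s = G^4/(G^4+KD)
GABAB = dict(k1=0.52, k2=0.0013, k3=0.098, k4=0.033, kd=100.0, n=4)

# Short-term depression of intracortical excitatory connections:
# on presynaptic spike E <- E*(1-U); recovery dE/dt = (1-E)/TAU
DEPRESSION_U = 0.07
DEPRESSION_TAU = 700.0  # ms

# Miniature PSPs: instantaneous release hazard (per ms) as a function of the
# time since the last presynaptic spike; saturates at MINI_RATE_MAX = 1/250.
MINI_RATE_TAU = 20.0     # ms, sigmoidal recovery constant
MINI_RATE_MAX = 1.0 / 250.0
# Quantal conductances (uS, per-target totals normalised like evoked synapses)
G_MINI = {"PY_PY": 0.033, "PY_IN": 0.02, "IN_PY": 0.02}

# ----------------------------------------------------------------------------
# Maximal synaptic conductances (uS), per-target totals
# ----------------------------------------------------------------------------
G_SYN = {
    ("PY", "PY", "AMPA"): 0.024,
    ("PY", "PY", "NMDA"): 0.001,
    ("PY", "IN", "AMPA"): 0.012,
    ("PY", "IN", "NMDA"): 0.001,
    ("IN", "PY", "GABAA"): 0.024,
    ("TC", "PY", "AMPA"): 0.02,
    ("TC", "IN", "AMPA"): 0.02,
    ("PY", "TC", "AMPA"): 0.005,
    ("PY", "RE", "AMPA"): 0.015,
    ("TC", "RE", "AMPA"): 0.05,
    ("RE", "TC", "GABAA"): 0.05,
    ("RE", "TC", "GABAB"): 0.02,
    ("RE", "RE", "GABAA"): 0.05,
}

# Connection radii (1-D topographic fan-out, target-layer units)
RADII = {
    ("PY", "PY"): 5,
    ("PY", "IN"): 5,   # not printed in the source table; chosen for IN drive
    ("IN", "PY"): 5,   # not printed in the source table; lineage default
    ("TC", "PY"): 10,
    ("TC", "IN"): 2,
    ("PY", "TC"): 10,
    ("PY", "RE"): 8,
    ("TC", "RE"): 8,
    ("RE", "TC"): 8,
    ("RE", "RE"): 5,   # not printed in the source table; lineage default
}

# Default population sizes
N_PY, N_IN, N_TC, N_RE = 500, 100, 100, 100
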