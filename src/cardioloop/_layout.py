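"""Flat-array layouts shared by the Python surface and the compiled kernels.

Everything the compiled right-hand side needs is packed into one float64
parameter vector; the constants below name the slots.  Keeping the layout in
a single module guarantees the Python dataclasses and the numba kernels can
never disagree about it.
"""
import numpy as np

# ---- walls (five one-patch walls) -------------------------------------
LA, RA, LVFW, IVS, RVFW = 0, 1, 2, 3, 4
N_WALLS = 5
WALL_NAMES = ("LA", "RA", "LVfw", "IVS", "RVfw")

# per-wall parameter slots
W_SF_ACT, W_K1, W_SF_PAS, W_DELAY, W_T_TW, W_V_WALL, W_AM_REF = range(7)
NWP = 7
PW0 = 0

# ---- valves (six flow connections incl. the two venous-atria ones) ----
VENRA, TV, PV, VENLA, MV, AV = 0, 1, 2, 3, 4, 5
N_VALVES = 6
VALVE_NAMES = ("VenRa", "TV", "PV", "VenLa", "MV", "AV")

V_A_OPEN, V_A_LEAK, V_LEN = range(3)
NVP = 3
PV0 = PW0 + N_WALLS * NWP  # 35

# ---- compartments (volume-state order) --------------------------------
C_LA, C_RA, C_LV, C_RV, C_SYART, C_SYVEN, C_PUART, C_PUVEN = range(8)
N_COMP = 8
COMP_NAMES = ("LA", "RA", "LV", "RV", "SyArt", "SyVen", "PuArt", "PuVen")

# upstream / downstream compartment of each valve connection
VALVE_UP = np.array([C_SYVEN, C_RA, C_RV, C_PUVEN, C_LA, C_LV], dtype=np.int64)
VALVE_DN = np.array([C_RA, C_RV, C_PUART, C_LA, C_LV, C_SYART], dtype=np.int64)

# ---- Tube0D vessels (compartments 4..7 in the same order) -------------
T_V_REF, T_P_REF, T_K, T_RZ = range(4)
NTP = 4
N_TUBES = 4
TUBE_NAMES = ("SyArt", "SyVen", "PuArt", "PuVen")
PT0 = PV0 + N_VALVES * NVP  # 53

# ---- ArtVen microcirculations -----------------------------------------
AV_SYS, AV_PULM = 0, 1
A_P0, A_QREF, A_KAV = range(3)
NAP = 3
PA0 = PT0 + N_TUBES * NTP  # 69

# ---- global scalars ----------------------------------------------------
(G_T_CYCLE, G_RHO, G_BAG_VREF, G_BAG_PADAPT, G_BAG_K, G_LS_REF, G_LS0_TOE,
 G_LS0_COL, G_C_TOE, G_LS_ISO, G_ACT_NORM, G_WP, G_TAUV, G_ROPEN,
 G_V_COLL, G_P_COLL) = range(16)
NGP = 16
PG0 = PA0 + 2 * NAP  # 75
N_PARAMS = PG0 + NGP  # 91

# ---- ODE state vector: 8 volumes, 6 valve flows, 6 valve openings ----
IQ0 = 8
IZ0 = 14
N_STATE = 20

# ---- auxiliary (algebraic) outputs recorded per timestep --------------
AUX_P0 = 0            # 8 compartment pressures
AUX_PPERI = 8
AUX_VS = 9
AUX_YS = 10
AUX_TSRES = 11        # TriSeg junction-force residual norm
AUX_TM0 = 12          # 5 wall midwall tensions
AUX_AM0 = 17          # 5 wall midwall areas
AUX_QAV_SYS = 22
AUX_QAV_PULM = 23
AUX_PDISS = 24        # instantaneous dissipated power
N_AUX = 25
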