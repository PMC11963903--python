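{
 "parameters": {
  "walls": {
   "LA": {
    "Sf_act": 13.0,
    "k1": 10.0,
    "Sf_pas": 800.0,
    "dt_act": 0.0,
    "t_twitch": 0.2,
    "V_wall": 14.0,
    "Am_ref": 78.0
   },
   "RA": {
    "Sf_act": 13.0,
    "k1": 10.0,
    "Sf_pas": 800.0,
    "dt_act": 0.0,
    "t_twitch": 0.2,
    "V_wall": 10.0,
    "Am_ref": 76.0
   },
   "LVfw": {
    "Sf_act": 90.0,
    "k1": 10.0,
    "Sf_pas": 800.0,
    "dt_act": 127.5,
    "t_twitch": 0.4,
    "V_wall": 87.0,
    "Am_ref": 105.0
   },
   "IVS": {
    "Sf_act": 90.0,
    "k1": 10.0,
    "Sf_pas": 800.0,
    "dt_act": 127.5,
    "t_twitch": 0.4,
    "V_wall": 38.0,
    "Am_ref": 55.0
   },
   "RVfw": {
    "Sf_act": 90.0,
    "k1": 10.0,
    "Sf_pas": 800.0,
    "dt_act": 127.5,
    "t_twitch": 0.4,
    "V_wall": 40.0,
    "Am_ref": 130.0
   }
  },
  "valves": {
   "VenRa": {
    "A_open": 8.0,
    "A_leak": 8.0,
    "L": 1.2
   },
   "TV": {
    "A_open": 7.0,
    "A_leak": 7e-10,
    "L": 1.4
   },
   "PV": {
    "A_open": 5.0,
    "A_leak": 5e-10,
    "L": 1.4
   },
   "VenLa": {
    "A_open": 8.0,
    "A_leak": 8.0,
    "L": 1.2
   },
   "MV": {
    "A_open": 6.0,
    "A_leak": 6e-10,
    "L": 1.4
   },
   "AV": {
    "A_open": 4.5,
    "A_leak": 4.5e-10,
    "L": 1.6
   }
  },
  "tubes": {
   "SyArt": {
    "V_ref": 550.0,
    "p_ref": 91.0,
    "k_tube": 8.0,
    "R_z": 0.8
   },
   "SyVen": {
    "V_ref": 3100.0,
    "p_ref": 6.0,
    "k_tube": 6.0,
    "R_z": 0.2
   },
   "PuArt": {
    "V_ref": 150.0,
    "p_ref": 16.0,
    "k_tube": 4.0,
    "R_z": 0.3
   },
   "PuVen": {
    "V_ref": 350.0,
    "p_ref": 8.0,
    "k_tube": 4.0,
    "R_z": 0.2
   }
  },
  "artvens": {
   "Sy": {
    "p0_artven": 88.89722564932644,
    "q_ref": 5.0,
    "k_av": 1.0
   },
   "Pu": {
    "p0_artven": 8.0,
    "q_ref": 5.0,
    "k_av": 1.0
   }
  },
  "t_cycle": 0.85,
  "rho": 1050.0,
  "V_ref_bag": 800.0,
  "p_adapt_bag": 1.0,
  "k_bag": 10.0,
  "Ls_ref": 2.0,
  "Ls0_toe": 1.8,
  "Ls0_col": 2.2,
  "c_toe": 0.02,
  "Ls_iso": 1.51,
  "Ls_act_norm": 0.4,
  "p_blend": 0.75,
  "r_open": 1.5,
  "tau_valve": 5.0,
  "V_collapse": 5.0,
  "p_collapse": 10.0,
  "version": "cardioloop-reference-1"
 },
 "state": {
  "y": [
   7.93269735420343e-05,
   5.4401750219499774e-05,
   0.00010606998516880945,
   7.79277063526128e-05,
   0.000532677519857255,
   0.002599872922771873,
   0.00012557334476542457,
   0.00030741466784799603,
   6.380881272883556e-05,
   1.2975767102424828e-05,
   -1.0476870953389533e-11,
   1.3884579074533118e-05,
   1.3644235339230068e-05,
   -1.8437253792832623e-13,
   0.999999833180994,
   0.9451946774060781,
   2.0713891628645345e-08,
   0.9681187132799804,
   0.9655404881125371,
   5.941503852952158e-47
  ],
  "triseg": [
   4.367931299402847e-05,
   0.034169223682127665
  ],
  "p0_artven_sys": 88.89722564932644,
  "calibration": {
   "p0_mmHg": 91.0,
   "q0_Lmin": 5.0,
   "e_steady": 1e-05,
   "beats": 189,
   "solver": {
    "method": "adams_moulton",
    "order": 2,
    "dt_ms": 1.0,
    "e_triseg": 0.0001,
    "newton_tol": 1e-10,
    "max_newton": 12
   },
   "p_art_mean_mmHg": 91.00087472572709,
   "q_venous_return_Lmin": 5.000048055261992
  }
 },
 "checksum": "df2730a5e2d4c67f"
}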