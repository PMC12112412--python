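treatment_id,n_rate,pdens,residue,n,yield_obs,sd_obs,yield_pred,sd_pred,acv_obs,acv_pred,syi_obs,syi_pred
T0-PDENS1-CRret,T0,PDENS1,CR_ret,8,0.30,0.11,0.25,0.10,31.6,51.9,0.25,0.13
T1-PDENS1-CRret,T1,PDENS1,CR_ret,8,0.52,0.13,0.44,0.24,27.1,48.8,0.51,0.18
T2-PDENS1-CRret,T2,PDENS1,CR_ret,8,0.52,0.18,0.48,0.31,37.3,53.9,0.43,0.15
T0-PDENS2-CRret,T0,PDENS2,CR_ret,8,0.26,0.10,0.27,0.11,37.7,45.1,0.21,0.20
T1-PDENS2-CRret,T1,PDENS2,CR_ret,8,0.46,0.19,0.37,0.17,40.6,43.5,0.36,0.26
T2-PDENS2-CRret,T2,PDENS2,CR_ret,8,0.47,0.16,0.40,0.20,35.2,46.0,0.39,0.25
T0-PDENS1-CRrmv,T0,PDENS1,CR_rmv,8,0.26,0.19,0.28,0.10,51.7,50.0,0.07,0.15
T1-PDENS1-CRrmv,T1,PDENS1,CR_rmv,8,0.55,0.22,0.49,0.28,48.6,50.0,0.37,0.17
T2-PDENS1-CRrmv,T2,PDENS1,CR_rmv,8,0.50,0.25,0.52,0.32,56.6,50.1,0.28,0.16
T0-PDENS2-CRrmv,T0,PDENS2,CR_rmv,8,0.28,0.23,0.28,0.09,52.7,40.1,0.07,0.22
T1-PDENS2-CRrmv,T1,PDENS2,CR_rmv,8,0.39,0.16,0.42,0.18,43.6,39.8,0.35,0.28
T2-PDENS2-CRrmv,T2,PDENS2,CR_rmv,8,0.46,0.18,0.45,0.20,55.4,40.4,0.42,0.29
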