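treatment_id,n_rate,season,n,yield_obs,sd_obs,yield_pred,sd_pred,acv_obs,acv_pred,syi_obs,syi_pred
N0-HDS,0,HDS,8,2.3,0.8,2.0,0.4,27.1,13.9,0.18,0.19
N60-HDS,60,HDS,8,5.1,0.7,5.2,0.4,14.9,8.1,0.51,0.61
N120-HDS,120,HDS,8,5.9,1.0,6.5,0.5,21.4,10.2,0.57,0.76
N180-HDS,180,HDS,8,6.6,1.1,7.5,0.4,21.0,8.4,0.65,0.89
N0-WS,0,WS,7,1.6,0.5,1.6,0.2,19.2,7.9,0.13,0.17
N60-WS,60,WS,7,3.8,0.9,3.9,0.4,22.6,9.7,0.35,0.44
N120-WS,120,WS,7,4.5,1.4,5.0,0.5,33.6,11.6,0.36,0.57
N180-WS,180,WS,7,4.6,1.5,5.4,0.8,34.1,16.5,0.37,0.59
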