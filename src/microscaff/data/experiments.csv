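matrix,id,f,speed,fan_pwm,pwm_note,failed,n_base_layers,pass_f,pass_speed,pass_pattern,notes
F,F1B,1.00,600,0,,False,,,,,
F,F2B,0.60,600,0,,False,,,,,
F,F3B,0.45,600,0,,False,,,,,
F,F4B,0.30,600,0,,False,,,,,
V,V1B,0.60,5000,0,,False,,,,,
V,V2B,0.60,6000,0,,False,,,,,
V,V3B,0.45,1200,0,,False,,,,,
V,V4B,0.45,3000,0,,False,,,,,
V,V5B,0.45,4200,0,,False,,,,,
V,V6B,0.60,5000,0,,False,,,,,
V,V7B,0.45,6000,0,,False,,,,,
V,V8B,0.30,1200,0,,True,,,,,first layer did not adhere to the bed
T,T1B,0.60,600,255,255 (100 %),False,,,,,
T,T2B,0.60,5000,150,150 (58.8 %),False,,,,,
T,T3B,0.60,5000,255,255 (100 %),False,,,,,
T,T4B,0.45,6000,50,50 (19.6%),False,,,,,
T,T5B,0.60,6000,150,150 (58.8 %),False,,,,,
T,T6B,0.60,6000,255,255 (100 %),False,,,,,
T,T7B,0.45,600,255,255 (100 %),False,,,,,
T,T8B,0.45,3000,255,255 (100 %),False,,,,,
T,T9B,0.45,4200,255,255 (100 %),False,,,,,
T,T10B,0.45,5000,255,255 (19.6%),False,,,,,printed percentage inconsistent with PWM 255
T,T11B,0.45,6000,50,50 (100 %),False,,,,,printed percentage inconsistent with PWM 50
T,T12B,0.45,6000,255,255 (19.6%),True,,,,,first layer did not adhere to the bed; printed percentage inconsistent with PWM 255
T,T13B,0.30,600,255,255 (100 %),True,,,,,first layer did not adhere to the bed
P,P1B,0.40,6000,255,,False,3,0.40,6000,parallel,
P,P2B,0.20,600,255,,False,3,0.20,600,parallel,
P,P3B,0.20,4200,255,,False,3,0.20,4200,parallel,
P,P4B,0.20,5000,255,,False,3,0.20,5000,parallel,
P,P5B,0.20,6000,255,,False,3,0.20,6000,parallel,
P,P6B,0.10,600,255,,False,3,0.10,600,parallel,
P,P7B,0.10,4200,255,,False,3,0.10,4200,parallel,
P,P8B,0.10,5000,255,,False,3,0.10,5000,parallel,
P,P9B,0.10,6000,255,,False,3,0.10,6000,parallel,
D,D1B,0.20,5000,255,,False,3,0.20,5000,diagonal,
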