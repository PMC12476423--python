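label,n_v,n_c,t2_ms,t3c_ms,Tc_ms,Tg_ms
Mesh 1,39042,1817,20.9,2.1,28.1,31.5
Mesh 2,81842,1817,20.9,4.0,30.1,31.5
Mesh 3,160052,1817,20.9,8.2,35.5,31.5
Mesh 4 / Case 3,256904,1817,20.9,13.1,39.7,31.5
Case 1,256904,576,8.6,13.0,26.9,13.9
Case 2,256904,929,11.6,13.1,30.1,19.4
Case 4,256904,3715,39.9,13.3,58.5,58.8
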