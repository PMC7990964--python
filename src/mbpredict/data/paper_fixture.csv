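condition_id,trial,n_avoid,n_approach
sequence_1x100V_end,0,37,43
sequence_1x100V_end,1,43,37
sequence_1x100V_end,2,51,29
sequence_1x100V_end,3,47,33
sequence_1x100V_end,4,40,40
sequence_1x100V_end,5,48,32
sequence_1x100V_end,6,45,35
sequence_1x100V_end,7,51,29
sequence_2x50V_end,0,45,35
sequence_2x50V_end,1,55,25
sequence_2x50V_end,2,56,24
sequence_2x50V_end,3,50,30
sequence_2x50V_end,4,47,33
sequence_2x50V_end,5,49,31
sequence_2x50V_end,6,46,34
sequence_2x50V_end,7,48,32
sequence_4x25V_end,0,39,41
sequence_4x25V_end,1,45,35
sequence_4x25V_end,2,42,38
sequence_4x25V_end,3,49,31
sequence_4x25V_end,4,54,26
sequence_4x25V_end,5,42,38
sequence_4x25V_end,6,40,40
sequence_4x25V_end,7,39,41
sequence_8x12.5V_end,0,40,40
sequence_8x12.5V_end,1,49,31
sequence_8x12.5V_end,2,46,34
sequence_8x12.5V_end,3,46,34
sequence_8x12.5V_end,4,41,39
sequence_8x12.5V_end,5,48,32
sequence_8x12.5V_end,6,46,34
sequence_8x12.5V_end,7,42,38
sequence_1x100V_beginning,0,41,39
sequence_1x100V_beginning,1,40,40
sequence_1x100V_beginning,2,36,44
sequence_1x100V_beginning,3,39,41
sequence_1x100V_beginning,4,30,50
sequence_1x100V_beginning,5,37,43
sequence_1x100V_beginning,6,39,41
sequence_1x100V_beginning,7,36,44
sequence_2x50V_beginning,0,42,38
sequence_2x50V_beginning,1,40,40
sequence_2x50V_beginning,2,46,34
sequence_2x50V_beginning,3,42,38
sequence_2x50V_beginning,4,48,32
sequence_2x50V_beginning,5,44,36
sequence_2x50V_beginning,6,40,40
sequence_2x50V_beginning,7,43,37
sequence_4x25V_beginning,0,41,39
sequence_4x25V_beginning,1,36,44
sequence_4x25V_beginning,2,36,44
sequence_4x25V_beginning,3,43,37
sequence_4x25V_beginning,4,38,42
sequence_4x25V_beginning,5,41,39
sequence_4x25V_beginning,6,38,42
sequence_4x25V_beginning,7,43,37
sequence_8x12.5V_beginning,0,36,44
sequence_8x12.5V_beginning,1,45,35
sequence_8x12.5V_beginning,2,40,40
sequence_8x12.5V_beginning,3,46,34
sequence_8x12.5V_beginning,4,43,37
sequence_8x12.5V_beginning,5,44,36
sequence_8x12.5V_beginning,6,47,33
sequence_8x12.5V_beginning,7,43,37
repeated_0.5x4x25V,0,40,40
repeated_0.5x4x25V,1,50,30
repeated_0.5x4x25V,2,45,35
repeated_0.5x4x25V,3,43,37
repeated_0.5x4x25V,4,42,38
repeated_0.5x4x25V,5,39,41
repeated_0.5x4x25V,6,42,38
repeated_0.5x4x25V,7,43,37
repeated_1x4x25V,0,44,36
repeated_1x4x25V,1,48,32
repeated_1x4x25V,2,46,34
repeated_1x4x25V,3,41,39
repeated_1x4x25V,4,49,31
repeated_1x4x25V,5,44,36
repeated_1x4x25V,6,47,33
repeated_1x4x25V,7,48,32
repeated_2x4x25V,0,56,24
repeated_2x4x25V,1,45,35
repeated_2x4x25V,2,49,31
repeated_2x4x25V,3,45,35
repeated_2x4x25V,4,47,33
repeated_2x4x25V,5,51,29
repeated_2x4x25V,6,46,34
repeated_2x4x25V,7,46,34
repeated_4x4x25V,0,44,36
repeated_4x4x25V,1,51,29
repeated_4x4x25V,2,54,26
repeated_4x4x25V,3,54,26
repeated_4x4x25V,4,43,37
repeated_4x4x25V,5,52,28
repeated_4x4x25V,6,43,37
repeated_4x4x25V,7,43,37
repeated_0.5x4x50V,0,58,22
repeated_0.5x4x50V,1,40,40
repeated_0.5x4x50V,2,46,34
repeated_0.5x4x50V,3,44,36
repeated_0.5x4x50V,4,45,35
repeated_0.5x4x50V,5,48,32
repeated_0.5x4x50V,6,50,30
repeated_0.5x4x50V,7,48,32
repeated_1x4x50V,0,56,24
repeated_1x4x50V,1,53,27
repeated_1x4x50V,2,53,27
repeated_1x4x50V,3,44,36
repeated_1x4x50V,4,48,32
repeated_1x4x50V,5,50,30
repeated_1x4x50V,6,56,24
repeated_1x4x50V,7,51,29
repeated_2x4x50V,0,53,27
repeated_2x4x50V,1,52,28
repeated_2x4x50V,2,50,30
repeated_2x4x50V,3,55,25
repeated_2x4x50V,4,46,34
repeated_2x4x50V,5,41,39
repeated_2x4x50V,6,52,28
repeated_2x4x50V,7,52,28
repeated_4x4x50V,0,54,26
repeated_4x4x50V,1,55,25
repeated_4x4x50V,2,51,29
repeated_4x4x50V,3,57,23
repeated_4x4x50V,4,55,25
repeated_4x4x50V,5,53,27
repeated_4x4x50V,6,48,32
repeated_4x4x50V,7,51,29
continuous_10s_25V,0,35,45
continuous_10s_25V,1,42,38
continuous_10s_25V,2,29,51
continuous_10s_25V,3,39,41
continuous_10s_25V,4,41,39
continuous_10s_25V,5,42,38
continuous_10s_25V,6,41,39
continuous_10s_25V,7,43,37
continuous_15s_25V,0,39,41
continuous_15s_25V,1,51,29
continuous_15s_25V,2,40,40
continuous_15s_25V,3,39,41
continuous_15s_25V,4,50,30
continuous_15s_25V,5,46,34
continuous_15s_25V,6,47,33
continuous_15s_25V,7,45,35
continuous_30s_25V,0,59,21
continuous_30s_25V,1,51,29
continuous_30s_25V,2,55,25
continuous_30s_25V,3,51,29
continuous_30s_25V,4,48,32
continuous_30s_25V,5,56,24
continuous_30s_25V,6,42,38
continuous_30s_25V,7,43,37
continuous_45s_25V,0,60,20
continuous_45s_25V,1,52,28
continuous_45s_25V,2,58,22
continuous_45s_25V,3,47,33
continuous_45s_25V,4,56,24
continuous_45s_25V,5,49,31
continuous_45s_25V,6,60,20
continuous_45s_25V,7,57,23
continuous_90s_25V,0,60,20
continuous_90s_25V,1,59,21
continuous_90s_25V,2,57,23
continuous_90s_25V,3,58,22
continuous_90s_25V,4,59,21
continuous_90s_25V,5,55,25
continuous_90s_25V,6,55,25
continuous_90s_25V,7,56,24
continuous_120s_25V,0,59,21
continuous_120s_25V,1,61,19
continuous_120s_25V,2,63,17
continuous_120s_25V,3,60,20
continuous_120s_25V,4,56,24
continuous_120s_25V,5,59,21
continuous_120s_25V,6,56,24
continuous_120s_25V,7,63,17
continuous_10s_50V,0,41,39
continuous_10s_50V,1,48,32
continuous_10s_50V,2,44,36
continuous_10s_50V,3,49,31
continuous_10s_50V,4,54,26
continuous_10s_50V,5,42,38
continuous_10s_50V,6,41,39
continuous_10s_50V,7,53,27
continuous_15s_50V,0,51,29
continuous_15s_50V,1,55,25
continuous_15s_50V,2,59,21
continuous_15s_50V,3,47,33
continuous_15s_50V,4,49,31
continuous_15s_50V,5,52,28
continuous_15s_50V,6,58,22
continuous_15s_50V,7,50,30
continuous_30s_50V,0,60,20
continuous_30s_50V,1,59,21
continuous_30s_50V,2,56,24
continuous_30s_50V,3,61,19
continuous_30s_50V,4,63,17
continuous_30s_50V,5,59,21
continuous_30s_50V,6,57,23
continuous_30s_50V,7,68,12
continuous_45s_50V,0,58,22
continuous_45s_50V,1,65,15
continuous_45s_50V,2,66,14
continuous_45s_50V,3,59,21
continuous_45s_50V,4,65,15
continuous_45s_50V,5,66,14
continuous_45s_50V,6,63,17
continuous_45s_50V,7,64,16
continuous_90s_50V,0,71,9
continuous_90s_50V,1,62,18
continuous_90s_50V,2,59,21
continuous_90s_50V,3,65,15
continuous_90s_50V,4,66,14
continuous_90s_50V,5,64,16
continuous_90s_50V,6,69,11
continuous_90s_50V,7,69,11
continuous_120s_50V,0,67,13
continuous_120s_50V,1,70,10
continuous_120s_50V,2,66,14
continuous_120s_50V,3,69,11
continuous_120s_50V,4,63,17
continuous_120s_50V,5,70,10
continuous_120s_50V,6,67,13
continuous_120s_50V,7,67,13
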