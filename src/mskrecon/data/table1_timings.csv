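region,sequence,orientation,ta_standard,ta_dl
shoulder,PD FS,axial,2:14,1:10
shoulder,PD FS,coronal,2:53,1:09
knee,PD FS,coronal,3:11,1:33
knee,PD FS,sagittal,3:11,1:33
lumbar spine,T1,sagittal,2:56,1:27
lumbar spine,T2 FS,sagittal,2:45,0:58
hip,PD FS,axial,3:02,1:32
hip,PD FS,coronal,2:01,1:33
ankle,PD FS,axial,2:25,1:54
ankle,PD FS,sagittal,1:47,1:45
hand,PD FS,coronal,2:23,0:36
hand,PD FS,axial,4:40,1:23
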