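construct,kind,z,z_se,v_half,v_half_se
WT,activation,2.8,0.1,-24.6,0.5
T425L,activation,2.6,0.1,-5.2,0.4
L524R,activation,2.1,0.1,-39.6,0.7
A527L,activation,2.9,0.5,-30.8,1.6
L529H,activation,2.8,0.3,-56.7,0.9
L532H,activation,3.0,0.4,-33.9,1.4
W563L,activation,3.3,0.4,-51.7,1.0
A614G,activation,3.3,0.1,-21.2,0.2
T618L,activation,2.7,0.2,-18.9,0.7
WT,inactivation,0.9,0.1,-61.8,0.7
T425L,inactivation,0.7,0.1,-34.8,1.1
L524R,inactivation,0.7,0.1,-89.6,1.5
A527L,inactivation,0.9,0.1,-78.6,0.6
L529H,inactivation,0.8,0.1,-77.5,1.6
L532H,inactivation,0.6,0.1,-86.6,1.5
W563L,inactivation,0.9,0.1,-60.7,0.7
A614G,inactivation,1.1,0.1,-69.7,2.0
T618L,inactivation,0.9,0.1,-63.0,0.7
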