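code,name,C1_l,C1_m,C1_u,C2_l,C2_m,C2_u,C3_l,C3_m,C3_u,C4_l,C4_m,C4_u,C5_l,C5_m,C5_u,C6_l,C6_m,C6_u
A1,PLA/Hydroxyapatite (PLA/HA),20.0,45.0,65.0,1.5,3.5,6.0,40.0,60.0,70.0,24.0,48.0,100.0,85.0,92.0,99.0,1.0,3.0,5.0
A2,PCL/Hydroxyapatite (PCL/HA),3.5,7.0,11.0,0.1,0.2,0.4,60.0,75.0,90.0,50.0,100.0,200.0,90.0,95.0,99.0,1.0,3.0,5.0
A3,PLGA/Bioactive Glass (PLGA/BG),2.0,5.0,15.0,0.5,1.0,3.0,80.0,90.0,95.0,4.0,8.0,12.0,90.0,96.0,99.0,3.0,5.0,7.0
A4,PLA/Carbon Nanotubes (PLA/CNT),35.0,47.0,60.0,1.2,1.7,2.5,20.0,40.0,50.0,24.0,48.0,72.0,75.0,85.0,90.0,5.0,7.0,9.0
A5,PLA/Magnesium (PLA/Mg),15.0,30.0,52.0,0.8,1.5,2.2,30.0,55.0,70.0,12.0,16.0,24.0,85.0,90.0,95.0,3.0,5.0,7.0
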