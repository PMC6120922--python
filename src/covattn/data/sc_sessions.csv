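session_id,structure,subject,hit_in_before,hit_out_before,hit_in_during,hit_out_during,latency_asym_ms,velocity_asym_degps,delta_det_asym_pct,scotoma_area_deg2,overlap_pct,center_dist_deg,scotoma_x_deg,scotoma_y_deg,injection_ul,significant_deficit
SC-01,SC,M,,,,,22.7,,12.8,19,0,5.3,5.4,2.6,0.3,
SC-02,SC,M,,,,,67,,22.1,158.4,79.6,2.3,10.4,2.3,0.4,
SC-03,SC,M,,,,,44.4,,8.9,221.5,71.5,4.1,9.0,0.1,0.3,
SC-04,SC,M,,,,,75.5,,30.1,221,84.3,5,6.5,0.9,0.4,
SC-05,SC,M,,,,,-6.9,,-1.9,11,3,4,10.3,-2.4,0.5,
SC-06,SC,M,,,,,6.1,,9.1,81.5,0,9.2,12.0,5.0,0.4,
SC-07,SC,M,,,,,17.8,,0,15.5,4.4,4.5,9.0,0.5,0.4,
SC-08,SC,M,,,,,52.2,,21.8,200.7,70.9,7.3,14.1,1.1,0.5,
SC-09,SC,M,,,,,53.1,,10.8,114.8,59.1,6.6,13.0,0.4,0.5,
SC-10,SC,M,,,,,28.3,,16.2,165,34.8,2.7,10.7,0.0,0.4,
SC-11,SC,M,,,,,46.6,,23.8,101.8,62.2,4.1,13.0,-1.4,0.4,
SC-12,SC,M,,,,,59.8,,10.2,46.5,36,5.3,13.9,0.2,0.5,
SC-13,SC,M,,,,,13.2,,2,49.3,1.7,6.3,12.9,-1.3,0.5,
SC-14,SC,M,,,,,59.2,,-1.7,293.8,96.6,3.7,13.5,1.1,0.5,
SC-15,SC,M,,,,,72.1,,33.7,272.8,75.9,7,13.5,2.5,0.5,
SC-16,SC,M,,,,,70.7,,27,237.3,94.8,4.6,13.4,0.0,0.5,
SC-17,SC,M,,,,,22,,-4.2,17.3,8,12.7,20.1,3.7,0.5,
SC-18,SC,M,,,,,4.4,,-2.7,14.2,5.6,4.1,10.8,2.8,0.5,
SC-19,SC,S,,,,,112.7,,38.7,96.3,70.8,10.7,18.0,4.7,0.4,
SC-20,SC,S,,,,,66.55,,2.2,77.5,11.5,3.5,6.25,3.0,0.3,
SC-21,SC,S,,,,,83.1,,35.2,55,26.5,4,11.3,3.3,0.4,
SC-22,SC,S,,,,,59.6,,35.2,178,54,2.2,9.5,2.8,0.3,
SC-23,SC,S,,,,,55.8,,18.8,201,63.3,4.1,10.9,5.1,0.3,
SC-24,SC,S,,,,,1.7,,7.9,23.1,12.2,4.5,11.3,-0.3,0.4,
SC-25,SC,S,,,,,49.2,,34.9,111.3,32.9,1.8,6.8,2.1,0.4,
SC-26,SC,S,,,,,0.1,,0.2,21.1,8.8,3.2,5.6,-0.1,0.4,
SC-27,SC,S,,,,,22.3,,16,25,0,12.6,21.5,1.7,0.4,
SC-28,SC,S,,,,,40,,17.2,142,44.2,5.2,7.5,8.1,0.3,
SC-29,SC,S,,,,,33.3,,15.8,115,63,4.8,13.0,0.6,0.4,
SC-30,SC,S,,,,,32.3,,19.9,100.5,45.3,6.7,4.1,-3.1,0.3,
SC-31,SC,S,,,,,53.6,,19.8,176.8,82.1,3.1,8.8,-1.5,0.4,
SC-32,SC,S,,,,,36.1,,15.8,121,39.9,1.7,7.6,2.7,0.5,
SC-33,SC,S,,,,,75,,16.2,67.8,77.9,2,10.2,2.5,0.5,
SC-34,SC,S,,,,,115,,21.4,232.1,65.5,7.6,16.2,-0.4,0.5,
SC-35,SC,S,,,,,50,,20.1,189.4,41.2,7.7,5.6,-5.4,0.4,
SC-36,SC,S,,,,,100,,28.7,95.5,52.2,8.6,14.9,6.3,0.5,
SC-37,SC,S,,,,,92.5,,26.4,195.2,65.3,9.1,2.6,-6.0,0.5,
SC-38,SC,S,,,,,110,,29.2,163.9,69.2,2,9.8,1.3,0.5,
SC-39,SC,S,,,,,110,,25.2,175.8,88.7,5.2,12.5,-0.8,0.5,
SC-40,SC,S,,,,,122.5,,25.4,210,91.2,6.8,3.0,6.1,0.5,
SC-41,SC,S,,,,,31.3,,36.2,81.2,88.5,1.2,8.7,2.2,0.4,
SC-42,SC,S,,,,,74.8,,25,74.7,90.7,2.3,5.7,0.6,0.5,
SC-43,SC,S,,,,,28.5,,31,130.3,23.3,7.8,10.5,-5.9,0.4,
SC-44,SC,S,,,,,50.3,,29.8,166.6,44.5,4.2,5.7,5.0,0.5,
SC-45,SC,S,,,,,102.8,,36.2,140.3,65.5,9.3,17.0,3.0,0.5,
SC-46,SC,S,,,,,60.4,,22.1,110.5,72.8,2.2,5.6,1.3,0.5,
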