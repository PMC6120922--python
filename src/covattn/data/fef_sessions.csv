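session_id,structure,subject,hit_in_before,hit_out_before,hit_in_during,hit_out_during,latency_asym_ms,velocity_asym_degps,delta_det_asym_pct,scotoma_area_deg2,overlap_pct,center_dist_deg,scotoma_x_deg,scotoma_y_deg,injection_ul,significant_deficit
FEF-01,FEF,M,,,,,89.3,,10.9,275.7,100,3.8,11.5,-3.8,1.5,
FEF-02,FEF,M,,,,,63,,14,141.2,62.3,7.1,14.9,1.3,1.5,
FEF-03,FEF,M,,,,,54.9,,6.9,115.6,45.2,3.2,6.0,-1.2,1.5,
FEF-04,FEF,M,,,,,39.9,,4.7,76.3,38.9,4.2,10.8,-1.5,1.5,
FEF-05,FEF,M,,,,,32.5,,-8.2,95.2,33.5,4,5.0,4.2,2,
FEF-06,FEF,M,,,,,35,,1.8,109.2,40.3,6.2,13.9,5.1,2,
FEF-07,FEF,M,,,,,84.4,,4,208,61.2,7.2,7.8,-5.5,3,
FEF-08,FEF,M,,,,,140,,21,259.3,94.8,7.4,10.4,-5.3,3.5,
FEF-09,FEF,S,,,,,83.3,,-2.2,198.8,76.2,2.8,6.0,1.5,1.5,
FEF-10,FEF,S,,,,,60,,-4.6,167.4,66.6,3,10.3,4.1,1.5,
FEF-11,FEF,S,,,,,52.5,,12.7,189.4,55,5.8,8.8,1.2,1.5,
FEF-12,FEF,S,,,,,45,,-4.8,86.9,77.1,1.3,8.0,3.3,1.5,
FEF-13,FEF,S,,,,,65,,8.6,145.7,55.5,4.5,12.2,2.5,1.5,
FEF-14,FEF,S,,,,,72.5,,9.8,90,33.2,2.4,6.2,3.8,1.5,
FEF-15,FEF,S,,,,,50,,-7.1,202.6,12,8.3,15.6,-1.0,1.6,
FEF-16,FEF,S,,,,,67.5,,-3.8,65.3,18.4,7,3.0,-1.4,2,
FEF-17,FEF,S,,,,,45,,2.9,103.2,40.5,1.1,8.8,0.8,2,
FEF-18,FEF,S,,,,,110,,12.5,155.6,50.2,5.6,12.7,-1.4,2,
FEF-19,FEF,S,,,,,100.8,,11.8,238.5,98.2,9.8,17.5,-0.3,2,
FEF-20,FEF,S,,,,,71.1,,-4,140.7,33.8,5.2,6.1,-3.4,2,
FEF-21,FEF,S,,,,,73.4,,-8.3,154,58.6,10.1,17.9,1.3,2,
FEF-22,FEF,S,,,,,86.7,,3.2,198.3,97.4,6.4,10.4,2.4,2,
FEF-23,FEF,S,,,,,116,,23.3,211.5,70.7,8.3,9.8,4.2,3,
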