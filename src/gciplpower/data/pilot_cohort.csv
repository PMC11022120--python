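case_id,laterality,metric,timepoint,value
1,OD,mgcipl_volume_mm3,baseline,0.62
1,OD,mgcipl_volume_mm3,m2,0.46
1,OD,mgcipl_volume_mm3,m6,0.37
1,OD,mgcipl_thickness_um,baseline,87.77
1,OD,mgcipl_thickness_um,m2,64.11
1,OD,mgcipl_thickness_um,m6,53.44
2,OD,mgcipl_volume_mm3,baseline,0.30
2,OD,mgcipl_volume_mm3,m2,0.25
2,OD,mgcipl_volume_mm3,m6,0.25
2,OD,mgcipl_thickness_um,baseline,41.66
2,OD,mgcipl_thickness_um,m2,33.77
2,OD,mgcipl_thickness_um,m6,32.55
3,OS,mgcipl_volume_mm3,baseline,0.58
3,OS,mgcipl_volume_mm3,m2,0.44
3,OS,mgcipl_volume_mm3,m6,0.44
3,OS,mgcipl_thickness_um,baseline,79.67
3,OS,mgcipl_thickness_um,m2,60.00
3,OS,mgcipl_thickness_um,m6,59.55
4,OD,mgcipl_volume_mm3,baseline,0.55
4,OD,mgcipl_volume_mm3,m2,0.31
4,OD,mgcipl_volume_mm3,m6,0.25
4,OD,mgcipl_thickness_um,baseline,75.22
4,OD,mgcipl_thickness_um,m2,43.44
4,OD,mgcipl_thickness_um,m6,35.01
1,OS,mgcipl_volume_mm3,baseline,0.62
1,OS,mgcipl_volume_mm3,m2,0.42
1,OS,mgcipl_volume_mm3,m6,0.37
1,OS,mgcipl_thickness_um,baseline,84.00
1,OS,mgcipl_thickness_um,m2,56.56
1,OS,mgcipl_thickness_um,m6,50.89
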