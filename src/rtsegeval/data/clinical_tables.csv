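# Per-patient geometric and dosimetric metrics of an 11-patient clinical
# prostate cohort, transcribed from a published clinical evaluation of
# deep-learning pelvic auto-segmentation (reference values, not computed
# by this package). DSC/HD metrics compare auto-segmented to manual
# contours; ci_manual / ci_unet are Paddick conformity indices of the
# plans optimized on manual and auto-segmented contours; gamma_pct is the
# 3%/3 mm global gamma pass rate with 10% dose cut-off.
patient,dsc_prostate,dsc_bladder,dsc_rectum,hdavg_prostate,hd95_prostate,hdavg_bladder,hd95_bladder,hdavg_rectum,hd95_rectum,ci_manual,ci_unet,gamma_pct
Pat11,0.90,0.96,0.90,1.4,4.5,1.0,2.3,1.2,4.0,0.87,0.78,91
Pat14,0.88,0.96,0.88,1.5,3.6,1.0,3.6,1.2,3.5,0.83,0.83,89
Pat27,0.86,0.97,0.91,1.5,3.7,0.9,2.2,1.1,3.0,0.83,0.75,88
Pat32,0.87,0.96,0.78,2.2,5.1,1.1,3.2,3.4,14.9,0.89,0.77,79
Pat43,0.85,0.94,0.90,1.7,4.2,1.5,3.2,1.2,3.3,0.83,0.78,93
Pat44,0.88,0.96,0.92,1.3,3.6,0.8,2.1,0.8,2.2,0.82,0.88,94
Pat52,0.83,0.97,0.92,2.0,5.5,0.9,2.3,1.4,3.5,0.84,0.69,77
Pat59,0.82,0.97,0.90,2.3,6.2,0.9,2.6,1.3,4.9,0.87,0.70,71
Pat81,0.91,0.97,0.87,1.2,3.4,0.9,2.1,1.8,8.3,0.88,0.82,87
Pat82,0.92,0.97,0.88,1.0,2.3,0.8,2.1,1.2,3.5,0.85,0.85,92
Pat90,0.85,0.97,0.91,1.6,4.3,0.8,2.1,1.0,2.9,0.81,0.72,74
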