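subject_id,age_group,mass_kg,height_cm,t_ext_nm,t_flex_nm
I001,I,88.10124346623789,191.76505627656383,273.4805279711454,183.04542676976394
I002,I,65.9156251719931,185.74250083381878,264.0555592828939,135.21156799164845
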