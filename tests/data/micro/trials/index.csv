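filename,subject_id,age_group,clothing,height_m,trial
I001_S_0.5m_t1.csv,I001,I,S,0.5,1
I001_S_0.5m_t2.csv,I001,I,S,0.5,2
I001_S_1m_t1.csv,I001,I,S,1.0,1
I001_S_1m_t2.csv,I001,I,S,1.0,2
I001_FP_0.5m_t1.csv,I001,I,FP,0.5,1
I001_FP_0.5m_t2.csv,I001,I,FP,0.5,2
I001_FP_1m_t1.csv,I001,I,FP,1.0,1
I001_FP_1m_t2.csv,I001,I,FP,1.0,2
I002_S_0.5m_t1.csv,I002,I,S,0.5,1
I002_S_0.5m_t2.csv,I002,I,S,0.5,2
I002_S_1m_t1.csv,I002,I,S,1.0,1
I002_S_1m_t2.csv,I002,I,S,1.0,2
I002_FP_0.5m_t1.csv,I002,I,FP,0.5,1
I002_FP_0.5m_t2.csv,I002,I,FP,0.5,2
I002_FP_1m_t1.csv,I002,I,FP,1.0,1
I002_FP_1m_t2.csv,I002,I,FP,1.0,2
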