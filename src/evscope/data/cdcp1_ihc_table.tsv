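variable	category	high	low
age	le50	9	21
age	gt50	20	28
grade	I	3	10
grade	II	0	1
grade	III	27	34
t_stage	T1	0	1
t_stage	T2	2	11
t_stage	T3	28	37
n_stage	N0	15	31
n_stage	N1	15	18
m_stage	M0	20	32
m_stage	M1	10	17
tnm_stage	I	0	1
tnm_stage	II	2	11
tnm_stage	III	18	20
tnm_stage	IV	10	17
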