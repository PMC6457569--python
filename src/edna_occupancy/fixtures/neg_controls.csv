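control_id,control_type,m_total,m_pos
field_1,field,16000,0
field_2,field,16000,0
filtration_1,filtration,16000,0
extraction_1,extraction,16000,0
ntc_1,ntc,86649,19
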