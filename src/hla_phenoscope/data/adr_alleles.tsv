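allele	drugs	reaction	population	citation
C*01:02	Methazolamide	SJS/TEN	Korean, Japanese	methazolamide_sjs
C*03:02	Allopurinol	DRESS, SJS/TEN	Korean, Vietnamese	allopurinol_scar
B*58:01	Allopurinol; Carbamazepine; Lamotrigine	SCAR, DRESS, SJS/TEN	Asian, European	allopurinol_scar
B*13:01	Dapsone; Phenytoin	HSS, DRESS, SJS/TEN	Asian	dapsone_hss
DPB1*03:01	Aspirin	Asthma	Korean	aspirin_asthma
B*15:02	Carbamazepine; Phenytoin; Lamotrigine	SJS/TEN	Asian	carbamazepine_sjs
B*35:01	Nevirapine	HSS, DRESS	Multiple ethnicities	nevirapine_hss
A*31:01	Carbamazepine; Lamotrigine	SCAR, DRESS, SJS/TEN	Multiple ethnicities	carbamazepine_scar
B*15:11	Carbamazepine	DRESS, SJS/TEN	Asian	carbamazepine_sjs
DRB1*01:01	Nevirapine	DRESS, HSS	Asian, Australian	nevirapine_hss
B*57:01	Abacavir; Flucloxacillin	DRESS, HSS, DILI	Multiple ethnicities	abacavir_hss
B*59:01	Methazolamide; Carbamazepine	SJS/TEN	Asian, Japanese	methazolamide_sjs
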