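ref_id	feature_class	label	positions
IsPETase	triad	ser,his,asp	160,237,206
IsPETase	clamp_anchor_1		87
IsPETase	clamp_anchor_2		185
IsPETase	oxyanion		87,161
IsPETase	subsite1		87,119,185
IsPETase	subsite2		89,159,161,214,238
IsPETase	extended_loop		238,239,240,241,242,243,244,245,246,247,248,249,250
IsPETase	loop_window	1	84,92
IsPETase	loop_window	2	115,124
IsPETase	loop_window	3	155,168
IsPETase	canonical_disulfide		203,239
IsPETase	canonical_disulfide		273,289
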