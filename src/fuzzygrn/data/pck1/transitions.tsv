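id	process	inputs	outputs
T_CAT8_ACT	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na	CAT8:up:strong:activation
T_PCK1_CAT8	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na;CAT8:tf:up:strong	PCK1:up:strong:activation
T_PCK1_ERT1	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na;ERT1:tf:up:na	PCK1:up:weak:activation
T_PCK1_GSM1	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na;GSM1:tf:up:na	PCK1:up:weak:activation
T_PCK1_RDS2	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na;RDS2:tf:up:na	PCK1:up:medium:activation
T_PCK1_SIP4	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na;SIP4:tf:up:medium	PCK1:up:medium:activation
T_SIP4_ACT	gluconeogenesis	glucose:signal:absent:na;ethanol:signal:present:na	SIP4:up:medium:activation
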