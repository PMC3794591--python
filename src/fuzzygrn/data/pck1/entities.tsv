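id	name	etype	parents
CAT8	Cat8p zinc-cluster activator	tf	
ERT1	Ert1p regulator of ethanol metabolism	tf	
GSM1	Gsm1p zinc-cluster regulator	tf	
PCK1	phosphoenolpyruvate carboxykinase	gene	
RDS2	Rds2p zinc-cluster regulator	tf	
SIP4	Sip4p zinc-cluster activator	tf	
carbon_source	carbon source	signal	
ethanol	ethanol	signal	non_fermentable_cs
fermentable_cs	fermentable carbon source	signal	carbon_source
glucose	glucose	signal	fermentable_cs
non_fermentable_cs	non-fermentable carbon source	signal	carbon_source
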