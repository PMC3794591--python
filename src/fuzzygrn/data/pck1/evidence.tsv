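transition_id	article	eclass	technique	quote
T_CAT8_ACT	PMID9001001	author_statement	review statement	Cat8p becomes active upon glucose depletion during growth on ethanol
T_PCK1_CAT8	PMID9001002	binding	ChIP	Cat8p occupies the PCK1 promoter under non-fermentative conditions
T_PCK1_CAT8	PMID9001003	expression	northern blot	PCK1 transcript strongly induced in a CAT8-dependent manner on ethanol
T_PCK1_ERT1	PMID9001008	binding	EMSA	Ert1p binds a carbon-source-responsive element upstream of PCK1
T_PCK1_ERT1	PMID9001009	expression	real-time PCR	PCK1 induction is reduced in ert1 deletion cells
T_PCK1_GSM1	PMID9001010	binding	ChIP	Gsm1p is enriched at the PCK1 promoter
T_PCK1_GSM1	PMID9001011	expression	microarray	gsm1 deletion lowers PCK1 expression on non-fermentable medium
T_PCK1_RDS2	PMID9001006	binding	ChIP	Rds2p binds the PCK1 promoter region during growth on ethanol
T_PCK1_RDS2	PMID9001007	expression	microarray	PCK1 expression drops in rds2 mutants under gluconeogenic conditions
T_PCK1_SIP4	PMID9001004	binding	EMSA	Sip4p binds carbon-source-responsive elements in the PCK1 promoter
T_PCK1_SIP4	PMID9001005	expression	lacZ-fusion	PCK1-lacZ activity depends on SIP4 during ethanol growth
T_SIP4_ACT	PMID9001001	author_statement	review statement	Sip4p is induced and activated under non-fermentative growth
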