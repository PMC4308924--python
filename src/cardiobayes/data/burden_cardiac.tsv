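# Rare-variant carrier proportions (allele frequency < 0.0005) in cases and
# population controls, per gene, syndrome and variant-class group, for the
# calculation of gene-level prior odds of pathogenicity.
# For five LQTS genes burdens come from a prospective clinical case series
# (preferred); other LQTS genes carry literature-derived case burdens (the
# printed literature estimate is a combined radical + non-radical carrier
# proportion, stored here under non_radical; no radical carriers were
# reported for these genes, stored as 0).  HCM and BrS case burdens are
# literature-derived; their control burden is left empty because the prior
# policy for these syndromes uses a fixed 1% benign burden.
gene	syndrome	class_group	case_burden	control_burden	source
KCNQ1	LQTS	non_radical	0.1784	0.003945	case_series
KCNQ1	LQTS	radical	0.0384	0.0002	case_series
KCNH2	LQTS	non_radical	0.1256	0.004825	case_series
KCNH2	LQTS	radical	0.0392	0	case_series
SCN5A	LQTS	non_radical	0.0584	0.0112	case_series
SCN5A	LQTS	radical	0.0028	0.0002	case_series
KCNE1	LQTS	non_radical	0.0124	0.0014	case_series
KCNE1	LQTS	radical	0.002	0	case_series
KCNE2	LQTS	non_radical	0.0052	0.0011	case_series
KCNE2	LQTS	radical	0.0004	0.0002	case_series
KCNQ1	LQTS	non_radical	0.421	0.003945	literature
KCNH2	LQTS	non_radical	0.388	0.004825	literature
SCN5A	LQTS	non_radical	0.090	0.0112	literature
KCNE1	LQTS	non_radical	0.010	0.0014	literature
KCNE2	LQTS	non_radical	0.010	0.0011	literature
KCNJ2	LQTS	non_radical	0.010	0.0026	literature
KCNJ2	LQTS	radical	0	0	literature
ANK2	LQTS	non_radical	0.010	0.0386	literature
ANK2	LQTS	radical	0	0	literature
CACNA1C	LQTS	non_radical	0.010	0.0112	literature
CACNA1C	LQTS	radical	0	0	literature
CAV3	LQTS	non_radical	0.010	0.0011	literature
CAV3	LQTS	radical	0	0.0002	literature
SCN4B	LQTS	non_radical	0.001	0.0017	literature
SCN4B	LQTS	radical	0	0.0006	literature
AKAP9	LQTS	non_radical	0.001	0.0393	literature
AKAP9	LQTS	radical	0	0.0005	literature
SNTA1	LQTS	non_radical	0.001	0.0043	literature
SNTA1	LQTS	radical	0	0.0003	literature
KCNJ5	LQTS	non_radical	0.001	0.0045	literature
KCNJ5	LQTS	radical	0	0	literature
MYBPC3	HCM	non_radical	0.375		literature
MYBPC3	HCM	radical	0.375		literature
MYH7	HCM	non_radical	0.250		literature
MYH7	HCM	radical	0.250		literature
TNNT2	HCM	non_radical	0.060		literature
TNNT2	HCM	radical	0.060		literature
TNNI3	HCM	non_radical	0.060		literature
TNNI3	HCM	radical	0.060		literature
SCN5A	BrS	non_radical	0.300		literature
SCN5A	BrS	radical	0.300		literature
CACNA1C	BrS	non_radical	0.010		literature
CACNA1C	BrS	radical	0.010		literature
CACNA2D1	BrS	non_radical	0.010		literature
CACNA2D1	BrS	radical	0.010		literature
CACNB2	BrS	non_radical	0.010		literature
CACNB2	BrS	radical	0.010		literature
GPD1L	BrS	non_radical	0.010		literature
GPD1L	BrS	radical	0.010		literature
KCND3	BrS	non_radical	0.010		literature
KCND3	BrS	radical	0.010		literature
KCNE3	BrS	non_radical	0.010		literature
KCNE3	BrS	radical	0.010		literature
SCN1B	BrS	non_radical	0.010		literature
SCN1B	BrS	radical	0.010		literature
SCN3B	BrS	non_radical	0.010		literature
SCN3B	BrS	radical	0.010		literature
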