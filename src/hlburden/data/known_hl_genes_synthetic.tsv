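gene_id	inheritance_class
HLGA001	DFNA
HLGA002	DFNA
HLGA003	DFNA
HLGA004	DFNA
HLGA005	DFNA
HLGA006	DFNA
HLGA007	DFNA
HLGA008	DFNA
HLGA009	DFNA
HLGA010	DFNA
HLGA011	DFNA
HLGA012	DFNA
HLGA013	DFNA
HLGA014	DFNA
HLGA015	DFNA
HLGA016	DFNA
HLGA017	DFNA
HLGA018	DFNA
HLGA019	DFNA
HLGA020	DFNA
HLGA021	DFNA
HLGA022	DFNA
HLGA023	DFNA
HLGA024	DFNA
HLGA025	DFNA
HLGA026	DFNA
HLGA027	DFNA
HLGA028	DFNA
HLGA029	DFNA
HLGA030	DFNA
HLGA031	DFNA
HLGA032	DFNA
HLGA033	DFNA
HLGA034	DFNA
HLGA035	DFNA
HLGA036	DFNA
HLGA037	DFNA
HLGA038	DFNA
HLGA039	DFNA
HLGA040	DFNA
HLGA041	DFNA
HLGA042	DFNA
HLGA043	DFNA
HLGA044	DFNA
HLGA045	DFNA
HLGA046	DFNA
HLGA047	DFNA
HLGA048	DFNA
HLGA049	DFNA
HLGA050	DFNA
HLGA051	DFNA
HLGA052	DFNA
HLGA053	DFNA
HLGA054	DFNA
HLGA055	DFNA
HLGA056	DFNA
HLGA057	DFNA
HLGA058	DFNA
HLGA059	DFNA
HLGA060	DFNA
HLGA061	DFNA
HLGA062	DFNA
HLGA063	DFNA
HLGA064	DFNA
HLGA065	DFNA
HLGA066	DFNA
HLGB001	DFNB
HLGB002	DFNB
HLGB003	DFNB
HLGB004	DFNB
HLGB005	DFNB
HLGB006	DFNB
HLGB007	DFNB
HLGB008	DFNB
HLGB009	DFNB
HLGB010	DFNB
HLGB011	DFNB
HLGB012	DFNB
HLGB013	DFNB
HLGB014	DFNB
HLGB015	DFNB
HLGB016	DFNB
HLGB017	DFNB
HLGB018	DFNB
HLGB019	DFNB
HLGB020	DFNB
HLGB021	DFNB
HLGB022	DFNB
HLGB023	DFNB
HLGB024	DFNB
HLGB025	DFNB
HLGB026	DFNB
HLGB027	DFNB
HLGB028	DFNB
HLGB029	DFNB
HLGB030	DFNB
HLGB031	DFNB
HLGB032	DFNB
HLGB033	DFNB
HLGB034	DFNB
HLGB035	DFNB
HLGB036	DFNB
HLGB037	DFNB
HLGB038	DFNB
HLGB039	DFNB
HLGB040	DFNB
HLGB041	DFNB
HLGB042	DFNB
HLGB043	DFNB
HLGB044	DFNB
HLGB045	DFNB
HLGB046	DFNB
HLGB047	DFNB
HLGB048	DFNB
HLGB049	DFNB
HLGB050	DFNB
HLGB051	DFNB
HLGB052	DFNB
HLGB053	DFNB
HLGB054	DFNB
HLGB055	DFNB
HLGB056	DFNB
HLGB057	DFNB
HLGB058	DFNB
HLGB059	DFNB
HLGB060	DFNB
HLGB061	DFNB
HLGB062	DFNB
HLGB063	DFNB
HLGB064	DFNB
HLGB065	DFNB
HLGB066	DFNB
HLGB067	DFNB
HLGB068	DFNB
HLGB069	DFNB
HLGB070	DFNB
HLGB071	DFNB
HLGB072	DFNB
HLGB073	DFNB
HLGB074	DFNB
HLGB075	DFNB
HLGB076	DFNB
HLGB077	DFNB
HLGB078	DFNB
HLGB079	DFNB
HLGB080	DFNB
HLGB081	DFNB
HLGB082	DFNB
HLGB083	DFNB
HLGB084	DFNB
HLGB085	DFNB
HLGB086	DFNB
HLGB087	DFNB
HLGB088	DFNB
HLGB089	DFNB
HLGB090	DFNB
HLGB091	DFNB
HLGB092	DFNB
HLGB093	DFNB
HLGB094	DFNB
HLGB095	DFNB
HLGB096	DFNB
HLGB097	DFNB
HLGX001	DFNA+B
HLGX002	DFNA+B
HLGX003	DFNA+B
HLGX004	DFNA+B
HLGX005	DFNA+B
HLGX006	DFNA+B
HLGX007	DFNA+B
HLGX008	DFNA+B
HLGX009	DFNA+B
HLGX010	DFNA+B
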