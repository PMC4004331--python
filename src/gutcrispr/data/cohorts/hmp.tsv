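individual_id	dataset
HMP001	HMP
HMP002	HMP
HMP003	HMP
HMP004	HMP
HMP005	HMP
HMP006	HMP
HMP007	HMP
HMP008	HMP
HMP009	HMP
HMP010	HMP
HMP011	HMP
HMP012	HMP
HMP013	HMP
HMP014	HMP
HMP015	HMP
HMP016	HMP
HMP017	HMP
HMP018	HMP
HMP019	HMP
HMP020	HMP
HMP021	HMP
HMP022	HMP
HMP023	HMP
HMP024	HMP
HMP025	HMP
HMP026	HMP
HMP027	HMP
HMP028	HMP
HMP029	HMP
HMP030	HMP
HMP031	HMP
HMP032	HMP
HMP033	HMP
HMP034	HMP
HMP035	HMP
HMP036	HMP
HMP037	HMP
HMP038	HMP
HMP039	HMP
HMP040	HMP
HMP041	HMP
HMP042	HMP
HMP043	HMP
HMP044	HMP
HMP045	HMP
HMP046	HMP
HMP047	HMP
HMP048	HMP
HMP049	HMP
HMP050	HMP
HMP051	HMP
HMP052	HMP
HMP053	HMP
HMP054	HMP
HMP055	HMP
HMP056	HMP
HMP057	HMP
HMP058	HMP
HMP059	HMP
HMP060	HMP
HMP061	HMP
HMP062	HMP
HMP063	HMP
HMP064	HMP
HMP065	HMP
HMP066	HMP
HMP067	HMP
HMP068	HMP
HMP069	HMP
HMP070	HMP
HMP071	HMP
HMP072	HMP
HMP073	HMP
HMP074	HMP
HMP075	HMP
HMP076	HMP
HMP077	HMP
HMP078	HMP
HMP079	HMP
HMP080	HMP
HMP081	HMP
HMP082	HMP
HMP083	HMP
HMP084	HMP
HMP085	HMP
HMP086	HMP
HMP087	HMP
HMP088	HMP
HMP089	HMP
HMP090	HMP
HMP091	HMP
HMP092	HMP
HMP093	HMP
HMP094	HMP
HMP095	HMP
HMP096	HMP
HMP097	HMP
HMP098	HMP
HMP099	HMP
HMP100	HMP
HMP101	HMP
HMP102	HMP
HMP103	HMP
HMP104	HMP
HMP105	HMP
HMP106	HMP
HMP107	HMP
HMP108	HMP
HMP109	HMP
HMP110	HMP
HMP111	HMP
HMP112	HMP
HMP113	HMP
HMP114	HMP
HMP115	HMP
HMP116	HMP
HMP117	HMP
HMP118	HMP
HMP119	HMP
HMP120	HMP
HMP121	HMP
HMP122	HMP
HMP123	HMP
HMP124	HMP
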