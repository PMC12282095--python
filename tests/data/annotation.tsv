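metabolite_id	origin	pathway_ids
M000	microbiota	path_scfa;path_bile
M001	microbiota	path_scfa
M002	microbiota	path_scfa
M003	microbiota	path_bile
M004	microbiota	path_bile
M005	co-metabolism	path_trp
M006	co-metabolism	path_trp
M007	co-metabolism	path_trp;path_phenyl
M008	co-metabolism	path_phenyl
M009	co-metabolism	path_phenyl
M010	host	path_lipid
M011	host	path_lipid
M012	food
M013	drug
M014	microbiota	path_bile
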