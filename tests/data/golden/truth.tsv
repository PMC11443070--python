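disease_id	phenotype_id	kind	lift
SD:000006	SP:000010	planted	8
SD:000007	SP:000011	planted	8
SD:000008	SP:000012	planted	8
SD:000009	SP:000013	planted	8
SD:000030	SP:000030	confounder	
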