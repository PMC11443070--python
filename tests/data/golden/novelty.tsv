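disease_id	phenotype_id	novel	laconic	significant
SD:000006	SP:000000	True	False	True
SD:000006	SP:000001	True	False	True
SD:000006	SP:000005	True	False	False
SD:000006	SP:000009	True	False	False
SD:000006	SP:000010	True	True	True
SD:000006	SP:000012	True	False	False
SD:000006	SP:000015	True	False	False
SD:000006	SP:000019	True	False	False
SD:000006	SP:000020	True	False	False
SD:000006	SP:000025	True	False	False
SD:000006	SP:000026	True	False	False
SD:000006	SP:000029	True	False	False
SD:000006	SP:000030	True	False	False
SD:000007	SP:000000	False	False	False
SD:000007	SP:000002	False	False	True
SD:000007	SP:000008	True	False	False
SD:000007	SP:000009	True	False	False
SD:000007	SP:000011	False	True	True
SD:000007	SP:000012	True	False	False
SD:000007	SP:000016	True	False	False
SD:000007	SP:000021	True	False	False
SD:000007	SP:000026	True	False	False
SD:000007	SP:000027	True	False	False
SD:000008	SP:000000	True	False	False
SD:000008	SP:000001	True	False	False
SD:000008	SP:000002	True	False	True
SD:000008	SP:000004	True	False	False
SD:000008	SP:000005	True	False	False
SD:000008	SP:000006	True	False	False
SD:000008	SP:000007	True	False	False
SD:000008	SP:000011	True	False	False
SD:000008	SP:000012	True	True	True
SD:000008	SP:000013	True	False	False
SD:000008	SP:000015	True	False	False
SD:000008	SP:000021	True	False	False
SD:000008	SP:000023	True	False	False
SD:000008	SP:000025	True	False	False
SD:000008	SP:000026	True	False	False
SD:000008	SP:000027	True	False	False
SD:000008	SP:000028	True	False	False
SD:000008	SP:000029	True	False	False
SD:000009	SP:000000	True	False	False
SD:000009	SP:000002	True	False	True
SD:000009	SP:000004	True	False	False
SD:000009	SP:000008	True	False	False
SD:000009	SP:000012	True	False	False
SD:000009	SP:000013	True	True	True
SD:000009	SP:000015	True	False	False
SD:000009	SP:000016	True	False	False
SD:000009	SP:000018	True	False	False
SD:000009	SP:000023	True	False	False
SD:000009	SP:000024	True	False	False
SD:000009	SP:000027	True	False	False
SD:000009	SP:000028	True	False	False
SD:000010	SP:000003	True	False	False
SD:000010	SP:000004	True	False	False
SD:000010	SP:000008	True	False	False
SD:000010	SP:000014	True	False	False
SD:000010	SP:000015	True	False	False
SD:000010	SP:000016	True	False	False
SD:000010	SP:000018	True	False	False
SD:000010	SP:000019	True	False	False
SD:000010	SP:000021	True	False	False
SD:000010	SP:000022	True	False	False
SD:000010	SP:000023	True	False	False
SD:000010	SP:000026	True	False	False
SD:000011	SP:000002	True	False	False
SD:000011	SP:000003	True	False	False
SD:000011	SP:000006	True	False	False
SD:000011	SP:000011	True	False	False
SD:000011	SP:000013	True	False	False
SD:000011	SP:000014	True	False	False
SD:000011	SP:000019	True	False	False
SD:000011	SP:000020	True	False	False
SD:000011	SP:000022	True	False	False
SD:000011	SP:000023	True	False	False
SD:000011	SP:000025	True	False	False
SD:000011	SP:000029	True	False	False
SD:000011	SP:000030	True	False	False
SD:000012	SP:000005	True	False	False
SD:000012	SP:000009	True	False	False
SD:000012	SP:000010	True	False	False
SD:000012	SP:000014	True	False	False
SD:000012	SP:000017	True	False	False
SD:000012	SP:000018	True	False	False
SD:000012	SP:000026	True	False	False
SD:000012	SP:000028	True	False	False
SD:000012	SP:000030	True	False	False
SD:000013	SP:000003	True	False	False
SD:000013	SP:000006	True	False	False
SD:000013	SP:000009	True	False	False
SD:000013	SP:000015	True	False	False
SD:000013	SP:000016	True	False	False
SD:000013	SP:000017	True	False	False
SD:000013	SP:000023	True	False	False
SD:000013	SP:000024	True	False	False
SD:000013	SP:000027	True	False	False
SD:000013	SP:000028	True	False	False
SD:000013	SP:000030	True	False	False
SD:000014	SP:000005	True	False	False
SD:000014	SP:000006	True	False	False
SD:000014	SP:000008	True	False	False
SD:000014	SP:000015	True	False	False
SD:000014	SP:000017	True	False	False
SD:000014	SP:000018	True	False	False
SD:000014	SP:000019	True	False	False
SD:000014	SP:000022	True	False	False
SD:000014	SP:000026	True	False	False
SD:000014	SP:000027	True	False	False
SD:000014	SP:000029	True	False	False
SD:000014	SP:000030	True	False	False
SD:000015	SP:000007	True	False	False
SD:000015	SP:000011	True	False	False
SD:000015	SP:000017	True	False	False
SD:000015	SP:000018	True	False	False
SD:000015	SP:000022	True	False	False
SD:000015	SP:000023	True	False	False
SD:000015	SP:000024	True	False	False
SD:000015	SP:000027	True	False	False
SD:000015	SP:000030	True	False	False
SD:000016	SP:000003	True	False	False
SD:000016	SP:000004	True	False	False
SD:000016	SP:000007	True	False	False
SD:000016	SP:000012	True	False	False
SD:000016	SP:000016	True	False	False
SD:000016	SP:000018	True	False	False
SD:000016	SP:000021	True	False	False
SD:000016	SP:000022	True	False	False
SD:000016	SP:000023	True	False	False
SD:000016	SP:000025	True	False	False
SD:000016	SP:000027	True	False	False
SD:000017	SP:000000	True	False	False
SD:000017	SP:000002	True	False	False
SD:000017	SP:000003	True	False	False
SD:000017	SP:000006	True	False	False
SD:000017	SP:000008	True	False	False
SD:000017	SP:000009	True	False	False
SD:000017	SP:000014	True	False	False
SD:000017	SP:000015	True	False	False
SD:000017	SP:000017	True	False	False
SD:000017	SP:000018	True	False	False
SD:000017	SP:000021	True	False	False
SD:000017	SP:000025	True	False	False
SD:000017	SP:000028	True	False	False
SD:000017	SP:000029	True	False	False
SD:000030	SP:000000	True	False	False
SD:000030	SP:000003	True	False	False
SD:000030	SP:000005	True	False	False
SD:000030	SP:000014	True	False	False
SD:000030	SP:000016	True	False	False
SD:000030	SP:000017	True	False	False
SD:000030	SP:000018	True	False	False
SD:000030	SP:000019	True	False	False
SD:000030	SP:000021	True	False	False
SD:000030	SP:000026	True	False	False
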