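accession	name	pval_early	ratio_early	pval_late	ratio_late	related_to_diabetes	kidney_expression
Q99MZ7	Peroxisomal trans-2-enoyl-CoA reductase	0.000311	0.485	0.00466	0.565	NO	YES
Q9DBM2	Peroxisomal bifunctional enzyme	0.000311	0.453	0.01	0.664	NO	YES
O09174	Alpha-methylacyl-CoA racemase	0.000622	0.52	0.00187	0.56	YES	YES
P11930	Nucleoside diphosphate-linked moiety X motif	0.000622	0.2499	0.000311	0.23	NO	YES
Q61847	Meprin A subunit beta	0.000622	0.408	0.00187	0.455	YES	YES
Q9DC50	Peroxisomal carnitine O-octanoyltransferase	0.00124	0.413	0.0122	0.296	YES	YES
Q5FW60	Major urinary protein 20	0.00215	only in wt	0.0324	only in wt	NO	NO
Q64462	Cytochrome P450 4B1	0.00218	0.387	0.00109	0.473	NO	NO
Q91WU0	Carboxylesterase 1F	0.00373	0.387	0.00466	0.579	NO	YES
Q9D826	Peroxisomal sarcosine oxidase	0.005905	0.566932	0.0499	0.615	YES	YES
Q9R0H0	Peroxisomal acyl-coenzyme A oxidase 1	0.00591	0.599	0.00109	0.496	YES	YES
P16015	Carbonic anhydrase 3	0.00721	only in wt	0.0071	0.119	NO	NO
Q3UBX0	Transmembrane protein 109	0.014	0.590	0.0289	0.289	NO	YES
Q8C0I1	Alkyldihydroxyacetonephosphate synthase, peroxisomal	0.0157	0.297	0.000682	0.08254	YES	YES
P03930	ATP synthase protein 8	0.0173	0.353	0.0287	0.0285	NO	NO
P28825	Meprin A subunit alpha	0.0205	0.326	0.000155	0.424	YES	YES
Q3UNX5	Acyl-coenzyme A synthetase ACSM3, mitochondrial	0.0289	0.431	0.00257	0.203	NO	YES
Q9DCC4	Pyrroline-5-carboxylate reductase 3	0.0356	0.537	0.0204	0.287	NO	YES
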