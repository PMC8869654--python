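accession	name	pval_early	ratio_early	pval_late	ratio_late	related_to_diabetes	kidney_expression
D3Z7P3	Glutaminase kidney isoform, mitochondrial	0.000311	2.94	0.000311	2.33	YES	YES
Q91W43	Glycine dehydrogenase (decarboxylating), mitochondrial	0.000311	2.16	0.000155	2.88	YES	YES
P02535	Keratin, type I cytoskeletal 10	0.00124	4.12	0.000155	3.62	NO	NO
O88986	2-amino-3-ketobutyrate coenzyme A ligase, mitochondrial	0.00214	3.54	0.00295	2.57	YES	YES
Q99K67	Alpha-aminoadipic semialdehyde synthase	0.00218	1.76	0.00295	2.57	YES	YES
P26645	Myristoylated alanine-rich C-kinase substrate	0.00314	2.21	0.00986	2.58	NO	YES
P01029	Complement C4-B	0.00897	5.57	0.00295	4.42	NO	NO
Q99L43	Phosphatidate cytidylyltransferase 2	0.0125	2.12	0.00295	1.92	NO	YES
P27546	Microtubule-associated protein 4	0.0128	6.06	0.0148	1.73	NO	YES
Q02013	Aquaporin-1	0.0128	2.23	0.00187	2.24	NO	YES
Q9JKV5	Secretory carrier-associated membrane protein 4	0.0173	2.065	0.033	2.59	NO	YES
P01872	Ig mu chain C region	0.0231	4.94	0.00147	14.0	NO	NO
Q3U9G9	Lamin-B receptor	0.0231	3.59	0.00817	2.284	NO	NO
O09111	NADH dehydrogenase [ubiquinone] 1 beta	0.0289	1.898	0.00699	1.94	YES
Q8BGA8	Acyl-coenzyme A synthetase ACSM5, mitochondrial	0.0289	1.52	0.000622	1.95	NO	YES
P11276	Fibronectin	0.0292	3.05	0.000554	103	YES	YES
O35682	Myeloid-associated differentiation marker	0.0321	2.85	0.00699	2.25	NO	NO
O70251	Elongation factor 1-beta	0.0321	1.76	0.00135	2.30	NO	YES
Q9ESD7	Dysferlin	0.0321	2.16	0.00377	4.55	NO	YES
Q8CFA2	Aminomethyltransferase, mitochondrial	0.04	2.17	0.00295	2.95	YES	YES
Q64669	NAD(P)H dehydrogenase [quinone] 1	0.043	6.96	0.01	1.60	NO	YES
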