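issn	title
1549-1676	PLOS Medicine
1932-6203	PLOS ONE
1553-7404	PLOS Genetics
1471-2458	BMC Public Health
1471-2288	BMC Medical Research Methodology
1741-7015	BMC Medicine
1471-2334	BMC Infectious Diseases
1471-2407	BMC Cancer
2044-6055	BMJ Open
2045-2322	Scientific Reports
1478-7954	Population Health Metrics
1476-069X	Environmental Health
2047-2978	Journal of Global Health
1742-4755	Reproductive Health
1475-2875	Malaria Journal
2050-7771	Biomarker Research
1708-8305	Journal of Travel Medicine
2051-1426	Journal for ImmunoTherapy of Cancer
1664-2392	Frontiers in Endocrinology
2296-2565	Frontiers in Public Health
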