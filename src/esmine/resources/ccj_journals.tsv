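issn	title
0028-4793	The New England Journal of Medicine
0140-6736	Lancet
0098-7484	JAMA
0959-8138	BMJ
0003-4819	Annals of Internal Medicine
0002-9343	The American Journal of Medicine
0003-9926	Archives of Internal Medicine
0012-3692	Chest
0009-7322	Circulation
0012-1797	Diabetes
0016-5085	Gastroenterology
0017-5749	Gut
0002-8703	American Heart Journal
0002-9149	The American Journal of Cardiology
0735-1097	Journal of the American College of Cardiology
0002-9262	American Journal of Epidemiology
0090-0036	American Journal of Public Health
0002-953X	The American Journal of Psychiatry
0004-3591	Arthritis and Rheumatism
0006-4971	Blood
0007-0963	The British Journal of Dermatology
0007-1161	The British Journal of Ophthalmology
0306-5251	British Journal of Clinical Pharmacology
0008-543X	Cancer
0009-9147	Clinical Chemistry
0149-5992	Diabetes Care
0013-9580	Epilepsia
0028-3878	Neurology
0029-7844	Obstetrics and Gynecology
0031-4005	Pediatrics
0032-5481	Postgraduate Medicine
0033-8419	Radiology
0036-8075	Science
0028-0836	Nature
0041-1337	Transplantation
0042-6822	Virology
0002-9378	American Journal of Obstetrics and Gynecology
0003-4932	Annals of Surgery
0003-4967	Annals of the Rheumatic Diseases
0099-2399	Journal of Endodontics
0022-1767	Journal of Immunology
0022-3476	The Journal of Pediatrics
0022-5347	The Journal of Urology
0025-7125	The Medical Clinics of North America
0027-8874	Journal of the National Cancer Institute
0029-6562	Nursing Research
1072-4710	Archives of Pediatrics and Adolescent Medicine
0003-9942	Archives of Neurology
0096-6762	Archives of Surgery
0003-9950	Archives of Ophthalmology
0885-3924	Journal of Pain and Symptom Management
0884-8734	Journal of General Internal Medicine
0304-3959	Pain
0954-6820	Journal of Internal Medicine
0022-2623	Journal of Medicinal Chemistry
0091-6749	The Journal of Allergy and Clinical Immunology
0021-9738	The Journal of Clinical Investigation
0022-1899	The Journal of Infectious Diseases
1058-4838	Clinical Infectious Diseases
0022-3018	The Journal of Nervous and Mental Disease
0163-8343	General Hospital Psychiatry
0002-838X	American Family Physician
0008-4409	CMAJ
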