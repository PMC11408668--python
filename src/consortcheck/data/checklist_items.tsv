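code	title	description	section_group	article_level	sentence_level	rare
1a	Title	Identification as a randomised trial in the title	TitleAbstract	1	0	0
1b	Abstract	Structured summary of trial design, methods, results, and conclusions	TitleAbstract	1	0	0
2a	Background	Scientific background and explanation of rationale	Introduction	0	0	0
2b	Objectives	Specific objectives or hypotheses	Introduction	0	1	0
3a	Trial Design	Description of trial design (such as parallel, factorial) including allocation ratio	Methods	0	1	0
3b	Changes to Trial Design	Important changes to methods after trial commencement (such as eligibility criteria), with reasons	Methods	0	1	1
4a	Eligibility Criteria	Eligibility criteria for participants	Methods	0	1	0
4b	Settings	Settings and locations where the data were collected	Methods	0	1	0
5	Interventions	The interventions for each group with sufficient details to allow replication, including how and when they were actually administered	Methods	0	1	0
6a	Outcomes	Completely defined pre-specified primary and secondary outcome measures, including how and when they were assessed	Methods	0	1	0
6b	Changes to Outcomes	Any changes to trial outcomes after the trial commenced, with reasons	Methods	0	1	1
7a	Sample Size Determination	How sample size was determined	Methods	0	1	0
7b	Interim Analyses and Stopping Guidelines	When applicable, explanation of any interim analyses and stopping guidelines	Methods	0	1	1
8a	Sequence Generation	Method used to generate the random allocation sequence	Methods	0	1	0
8b	Randomisation Type	Type of randomisation; details of any restriction (such as blocking and block size)	Methods	0	1	0
9	Allocation Concealment Mechanism	Mechanism used to implement the random allocation sequence (such as sequentially numbered containers), describing any steps taken to conceal the sequence until interventions were assigned	Methods	0	1	1
10	Implementation	Who generated the random allocation sequence, who enrolled participants, and who assigned participants to interventions	Methods	0	1	0
11a	Blinding	If done, who was blinded after assignment to interventions (for example, participants, care providers, those assessing outcomes) and how	Methods	0	1	0
11b	Similarity of Interventions	If relevant, description of the similarity of interventions	Methods	0	1	1
12a	Statistical Methods for Outcomes	Statistical methods used to compare groups for primary and secondary outcomes	Methods	0	1	0
12b	Statistical Methods for Other Analyses	Methods for additional analyses, such as subgroup analyses and adjusted analyses	Methods	0	1	1
13a	Participant Flow	For each group, the numbers of participants who were randomly assigned, received intended treatment, and were analysed for the primary outcome	Results	0	1	0
13b	Losses and Exclusions	For each group, losses and exclusions after randomisation, together with reasons	Results	0	1	0
14a	Recruitment	Dates defining the periods of recruitment and follow-up	Results	0	1	0
14b	Trial Stopping	Why the trial ended or was stopped	Results	0	1	1
15	Baseline Data	A table showing baseline demographic and clinical characteristics for each group	Results	0	1	0
16	Numbers Analysed	For each group, number of participants (denominator) included in each analysis and whether the analysis was by original assigned groups	Results	0	1	0
17a	Outcome Results	For each primary and secondary outcome, results for each group, and the estimated effect size and its precision (such as 95% confidence interval)	Results	0	1	0
17b	Binary Outcome Results	For binary outcomes, presentation of both absolute and relative effect sizes is recommended	Results	0	1	0
18	Ancillary Analyses	Results of any other analyses performed, including subgroup analyses and adjusted analyses, distinguishing pre-specified from exploratory	Results	0	1	0
19	Harms	All important harms or unintended effects in each group	Results	0	1	0
20	Limitations	Trial limitations, addressing sources of potential bias, imprecision, and, if relevant, multiplicity of analyses	Discussion	0	1	0
21	Generalisability	Generalisability (external validity, applicability) of the trial findings	Discussion	0	1	1
22	Interpretation	Interpretation consistent with results, balancing benefits and harms, and considering other relevant evidence	Discussion	0	1	0
23	Registration	Registration number and name of trial registry	OtherInformation	0	1	0
24	Protocol	Where the full trial protocol can be accessed, if available	OtherInformation	0	1	0
25	Funding	Sources of funding and other support (such as drugs), role of funders	OtherInformation	0	1	0
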