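# Curated list of canonical National Library of Medicine structured-abstract
# section labels (uppercase, one per line). Snapshot transcribed 2026-09 from
# the NLM structured-abstract label mappings; override with your own file via
# configuration if a different snapshot is needed.
AIM
AIMS
AIMS AND OBJECTIVES
ANALYSIS
BACKGROUND
BACKGROUND AND AIMS
BACKGROUND AND OBJECTIVES
BACKGROUND AND PURPOSE
CASE PRESENTATION
CLINICAL IMPLICATIONS
CLINICAL RELEVANCE
CLINICAL TRIAL REGISTRATION
CONCLUSION
CONCLUSIONS
CONCLUSIONS AND IMPLICATIONS
CONCLUSIONS AND RELEVANCE
CONTEXT
DATA ANALYSIS
DATA COLLECTION
DATA EXTRACTION
DATA SOURCES
DATA SYNTHESIS
DESIGN
DESIGN AND METHODS
DESIGN AND SETTING
DISCUSSION
DISCUSSION AND CONCLUSIONS
ELIGIBILITY CRITERIA
ETHICS AND DISSEMINATION
EXPERIMENTAL DESIGN
EXPOSURES
FINDINGS
FUNDING
HYPOTHESIS
IMPLICATIONS
IMPORTANCE
INTERPRETATION
INTERVENTION
INTERVENTIONS
INTRODUCTION
LIMITATIONS
MAIN OUTCOME MEASURES
MAIN OUTCOMES AND MEASURES
MAIN RESULTS
MATERIALS AND METHODS
MEASUREMENTS
MEASUREMENTS AND MAIN RESULTS
METHOD
METHODOLOGY
METHODS
METHODS AND ANALYSIS
METHODS AND RESULTS
OBJECT
OBJECTIVE
OBJECTIVES
OUTCOME MEASURES
OUTCOMES
PARTICIPANTS
PATIENTS
PATIENTS AND METHODS
PRIMARY OUTCOME
PROCEDURES
PURPOSE
RATIONALE
RECENT FINDINGS
REGISTRATION
RESEARCH DESIGN AND METHODS
RESULTS
SAMPLE
SEARCH METHODS
SEARCH STRATEGY
SELECTION CRITERIA
SETTING
SETTINGS
SIGNIFICANCE
STATISTICAL ANALYSIS
STUDY DESIGN
STUDY DESIGN AND METHODS
STUDY OBJECTIVE
STUDY SELECTION
SUBJECTS
SUBJECTS AND METHODS
SUMMARY
TRIAL DESIGN
TRIAL REGISTRATION
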