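# Small general-English synonym table (word<TAB>synonym|synonym|...).
# Backs the default SynonymProvider for EDA-style perturbation; entries are
# restricted to vocabulary common in clinical-trial prose.
big	large|sizable
large	big|substantial
small	little|minor
little	small|slight
study	trial|investigation
trial	study|experiment
investigation	study|inquiry
assess	evaluate|measure
evaluate	assess|appraise
measure	assess|quantify
compare	contrast
primary	principal|main
main	primary|principal
secondary	ancillary
outcome	endpoint|result
endpoint	outcome
result	outcome|finding
finding	result|observation
participants	subjects|patients
subjects	participants
patients	participants
group	arm|cohort
arm	group
cohort	group
treatment	intervention|therapy
intervention	treatment
therapy	treatment
drug	medication|agent
medication	drug
random	chance
randomly	arbitrarily
allocation	assignment
assignment	allocation
assigned	allocated
allocated	assigned
concealed	hidden|masked
hidden	concealed
blinded	masked
masked	blinded
eligible	qualified
eligibility	qualification
criteria	requirements
enrolled	recruited|registered
recruited	enrolled
recruitment	enrollment
baseline	initial
initial	baseline|first
follow	pursue
final	last|concluding
significant	notable|meaningful
notable	significant
effect	impact|influence
impact	effect
difference	disparity
increase	rise|gain
decrease	decline|reduction
reduction	decrease|decline
improvement	gain|amelioration
adverse	harmful|unfavorable
harmful	adverse
severe	serious|grave
serious	severe
mild	slight
moderate	intermediate
analysis	evaluation|examination
analyses	evaluations
statistical	quantitative
method	procedure|technique
methods	procedures|techniques
procedure	method|protocol
protocol	procedure|plan
design	plan|scheme
plan	design|scheme
data	observations
collected	gathered
gathered	collected
reported	documented|recorded
documented	reported|recorded
recorded	documented
observed	noted|seen
noted	observed
performed	conducted|carried
conducted	performed
completed	finished
finished	completed
received	got|obtained
obtained	received|acquired
provided	supplied|given
supplied	provided
determined	established|ascertained
established	determined
calculated	computed
computed	calculated
estimated	approximated
approximately	roughly|about
roughly	approximately
duration	period|length
period	duration|interval
interval	period
frequency	rate
rate	frequency
proportion	fraction|share
fraction	proportion
total	overall|aggregate
overall	total
mean	average
average	mean
median	midpoint
important	crucial|vital
crucial	important|vital
relevant	pertinent
pertinent	relevant
appropriate	suitable|fitting
suitable	appropriate
sufficient	adequate|enough
adequate	sufficient
limited	restricted
restricted	limited
excluded	omitted|removed
omitted	excluded
included	incorporated
withdrew	dropped|quit
discontinued	stopped|halted
stopped	halted|discontinued
halted	stopped
began	started|commenced
started	began|commenced
commenced	began|started
ended	concluded|finished
concluded	ended
continued	persisted|proceeded
monitored	tracked|observed
tracked	monitored
screened	checked|examined
examined	inspected|checked
inspected	examined
hospital	clinic|center
clinic	hospital
center	site|facility
site	center|location
location	site|place
country	nation
region	area|zone
area	region|zone
adults	grownups
children	kids|minors
women	females
men	males
age	years
older	elder
younger	junior
healthy	well|fit
disease	illness|condition
illness	disease|sickness
condition	disease|state
symptom	sign|indication
symptoms	signs|indications
diagnosis	identification
chronic	persistent|longstanding
persistent	chronic|lasting
acute	sudden|severe
risk	hazard|danger
hazard	risk|danger
benefit	advantage|gain
advantage	benefit
harm	damage|injury
damage	harm|injury
safety	security
efficacy	effectiveness
effectiveness	efficacy
quality	caliber|grade
funding	financing|support
financing	funding
support	backing|aid
sponsor	backer|funder
registry	register|database
registered	enrolled|listed
database	registry|repository
available	accessible|obtainable
accessible	available
generalisability	applicability
applicability	relevance
limitations	shortcomings|weaknesses
shortcomings	limitations
bias	prejudice|skew
interpretation	reading|understanding
evidence	proof|support
dose	dosage|amount
dosage	dose
daily	everyday
weekly	hebdomadal
placebo	dummy
control	comparison
standard	conventional|usual
conventional	standard|usual
usual	standard|customary
novel	new|innovative
new	novel|fresh
previous	prior|earlier
prior	previous|earlier
earlier	previous|prior
subsequent	later|following
later	subsequent
following	subsequent|ensuing
additional	extra|further
extra	additional|further
further	additional
several	various|numerous
various	several|diverse
numerous	many|several
many	numerous
few	handful
each	every
every	each
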