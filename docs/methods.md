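# Methods

This note documents the models and procedures implemented in
`comotraj`, the parameters that matter, what the synthetic registry
does and does not emulate, and the numerical and design choices made
where the design was genuinely open.

## Cohort definition and diagnosis events

The unit of raw data is one in-patient stay: pseudonymous patient id,
sex, age at admission in 5-year bands, ISO admission/release dates,
release type (discharge / transfer / death), and an ordered list of
three-character ICD-10 codes (primary first). Analysis restricts to the
disease categories A00–N99 — 1081 categories in the WHO catalogue,
carried as a documented constant; codes themselves are validated
structurally (letter + two digits, string-range check), not against the
official catalogue.

A wash-out period (default 1997–2002) drops every patient with any
admission in those years; this both fixes a comparable "healthy at
baseline" state and confines the data to a single ICD revision.
Remaining stays within the observation window (2003–2014) collapse to
*diagnosis events*: one row per distinct (patient, code, ten-year age
group, year); primary and secondary diagnoses are treated identically.
Ten-year age groups 1–8 cover ages 0–79 (derived from the 5-year band's
lower bound); stays at ages 80+ fall outside the layer universe and are
excluded. A hospitalization whose codes are all out of range emits one
sentinel event (code U99, configurable off), so the patient still
counts as hospitalized in that layer's denominators; the sentinel is
the vocabulary's 1082nd code.

Only the admission year is used for windowing. Patients can legitimately
appear in two adjacent age groups across different stays (5-year bands
straddle the decade boundary).

## Multilayer comorbidity network

Nodes are (code, age group) pairs; the analysis runs separately per
sex. Two link types:

**Intralayer links** (same layer). For every code pair the cohort is
stratified into six 2-year calendar windows. A stratum's 2×2 table
counts distinct patients of that sex with ≥ 1 event in that layer and
window (a = both codes, b/c = one, d = neither); a stratum is usable
when every cell holds at least `min_cell_count` = 5 patients. Usable
strata pool into the Mantel–Haenszel risk ratio

    RR_MH = [Σ_k a_k (c_k + d_k) / N_k] / [Σ_k c_k (a_k + b_k) / N_k]

with the Cochran–Mantel–Haenszel chi-square test (1 df, no continuity
correction) for independence. Pairs with RR > 1.5 and p < 0.05 in at
least one orientation become a bidirectional link: two directed edges,
each weighted by its own orientation of the pooled RR (risk of the
target given the source). The significance test is symmetric, so one
gate covers both directions. An infinite RR (zero pooled denominator)
is capped at `rr_cap` = 100 for the edge weight. No multiple-testing
correction is applied by default; a Benjamini–Hochberg flag exists.

**Interlayer links** (lower to higher layer). The observation period
splits into equally long frames T1 = 2003–2008 and T2 = 2009–2014, and

    w(i@α → j@β) = P(j in β during T2 | i in α during T1)
                   / P(j in β during T2),   α < β,

with probabilities over cohort patients of the sex observed (≥ 1 event)
in β during T2. Links are kept when the ratio exceeds 1.5 with ≥ 5
exposed patients; i = j is allowed and encodes disease persistence
across decades. Links run only forward in age: patients age forward
between the frames, and trajectory semantics need temporal order.
There is no significance test on these ratios; with small exposed
counts they are noisy, which is visible in the synthetic studies as
spurious interlayer links (see Limitations).

**Filtering and normalization.** Nodes without any intralayer link are
removed first, then nodes lacking an inbound or an outbound link,
iterated to a fixed point (mode `both_stages`; each stage is available
alone). Finally every node's incoming weights are divided by their sum
separately per link type, re-verified to 1 ± 1e-9. Note the
normalization is purely combinatorial: a node's sole incoming link of a
type gets weight 1.0 regardless of the strength of evidence behind it.

`network_summary` reports node/link counts, mean degree, degree
assortativity, average path length (largest connected component,
flagged when the network is disconnected), mean betweenness/closeness,
clustering, density, modularity of a greedy reference partition on the
undirected collapse, and per-layer breakdowns.

## Overlapping community detection

Intralayer and interlayer links are merged into one weighted undirected
graph (the fitness function cannot distinguish types); directed pairs
are symmetrized by summing the two normalized weights (max/mean are
config options). The fitness of a community G is

    f_G = k_in / (k_in + k_out)^a ,  a = 1,

with k_in the total internal weighted degree of members (each internal
edge counted from both ends) and k_out the weight crossing the
boundary. The *natural community* of a seed grows greedily: add the
neighbor with the largest positive gain, then sweep members, removing
any whose removal raises f, until the sweep is stable; stop when no
addition helps. Ties break lexicographically by node id, improvements
below 1e-12 count as none, a singleton with k_in = 0 has fitness 0, and
the seed itself may be swept out. Detection grows the natural
community of every node and removes duplicate member sets; a node left
uncovered (its own growth swept it out and nothing else contains it)
gets a second, seed-protected pass, so the cover is total. The result
is deterministic and independent of any RNG seed under lexicographic
ordering.

## Trajectories and pair relations

Each community is a trajectory X = {(i, α), …}. Similarity is the
Jaccard index over tuples — the same code in different age groups does
not overlap. For a pair X, Y with earliest layers α_min^X, α_min^Y and
latest layers α_max^X, α_max^Y:

* *identical*: equal sets (exclusive label);
* *nested*: proper subset either way;
* *diverging*: the overlap at X's earliest layer united with the
  overlap at Y's earliest layer is non-empty, and the tuple sets
  strictly above each of those layers differ;
* *converging*: the mirror image at the latest layers;
* *persistent*: the shared tuples all sit in one layer that is the
  highest of one trajectory and the lowest of the other;
* *unrelated*: none of the above.

Diverging and converging can co-occur and both labels are kept.
Frequency tables are emitted in two counting modes: independent (a pair
may count under several labels) and exclusive (precedence nested >
diverging > converging > persistent), since headline counts in the
field are usually exclusive-looking.

## Outcomes and critical events

A patient *follows* trajectory X in age group g when their events cover
at least half (inclusive) of X's tuples with layer ≤ g — future tuples
cannot penalize — and they have ≥ 1 event at g. Note the inclusive
boundary makes follower sets non-monotone under removal of held tuples.
Per trajectory × age group the pipeline reports followers, mean
hospital days (stay length = release − admission in days, same-day
stays floored at 1, configurable), mean stays, mean distinct diagnoses
(per age group by default, per stay by flag), and the mortality

    M = Σ_i m_i Π_{j≠i} (1 − m_j)

over the trajectory's member diagnoses of that age group, where m_i is
the in-hospital mortality of diagnosis i in that age group (deaths
among carriers / carriers; a patient is a death in a group when any of
their stays there ends in death; diagnoses without carriers are
excluded with a warning). M is the exactly-one-death probability: it is
monotone and ≈ Σ m_i for small m_i, but *decreases* again when many
large m_i combine — interpret it only in the small-m regime it is meant
for.

For every diverging pair, per-age-group ratios (first vs second branch,
order fixed by id) of mean diagnoses, days, stays and mortality are
computed; missing or zero denominators yield missing ratios. The split
layer is the highest layer among the shared tuples at the pair's common
start; the pair is flagged as a *critical event* when any ratio after
the split is ≥ 1.5 or ≤ 1/1.5 (threshold configurable — the underlying
notion is "considerably higher burden", which has no canonical value).

## Synthetic registry

The generator emulates the registry schema over 1997–2014 with known
ground truth; it is a study instrument, not a national epidemiology
model.

*Demographics and timing.* Each patient draws a uniform age 0–79 at
2003 (fixing a birth year), a sex, and traverses the age-group layers
whose years intersect the observation window. Stays of a patient-layer
are placed uniformly over its feasible calendar years; stay counts per
layer are 1 + Poisson(0.7); stay lengths are log-normal (μ=1, σ=0.8
log-days). Every visited patient-layer is hospitalized; a patient with
no drawn in-range diagnosis receives an out-of-range encounter
placeholder (Z76 → sentinel at ingestion) so stratum denominators match
the analytic model exactly.

*Background morbidity.* Each (code, layer) has a baseline prevalence;
presence persists into the next layer with probability ρ = 0.4
(chronic-disease recurrence), with the innovation rate chosen so every
layer's marginal equals its configured prevalence (prevalence 0 is
absorbing: the code cannot occur there). Codes are independent of each
other in the background.

*Planted modules.* A module is a latent patient class: members
(probability π) express each module code of a layer with probability m,
non-members show the background baseline p0; module activity enters the
module's first layer and proceeds to the next with `progression_prob`.
Given π, p0 and a target within-layer relative risk, m is solved (by
Brent's method) from the conditional-independence identity so the
single-stratum RR of any two module codes equals the target in
expectation; an unattainable target raises a config error naming the
module. For active members, module-code presence is *exactly* m (the
background-persistence latent is tracked separately), keeping the
calibration exact. Branch families (`branch_of`) share their
lowest-layer codes, assign each family member to exactly one branch,
and so plant a diverging trajectory pair. In-hospital deaths draw from
per-(code, layer) mortalities on the patient's last stay of the layer
and truncate the record. A configurable fraction of extra patients
(default 5%) receives a wash-out-period stay to exercise the cohort
filter. All randomness flows through one seeded generator; a fixed
seed reproduces the registry bit for bit.

*What it does not emulate:* realistic national disease frequencies or
age profiles, coding-practice/billing artifacts, correlated background
comorbidity beyond the planted modules, outpatient care, seasonal
admission patterns, or the official ICD-10 catalogue's gaps. Passing
recovery studies therefore show that the pipeline recovers the kinds of
structure it models under controlled noise — not that it is robust to
every artifact of real claims data.

## Canonical recovery studies

All studies use a cohort of 20,000 patients in a single analyzed sex
stratum (the pipeline is sex-stratified; the stratum size is the
operative sample size) and the default thresholds above.

* **Type-I control** — no modules planted, 24 background codes at
  prevalences 0.06–0.25 in all layers: the intralayer link emission
  rate over pairs with ≥ 1 usable stratum (≈ 2,200 tested pairs)
  measures the joint RR ∧ p gate's false-positive rate; it sits near
  1%, well under the 5% nominal level, because the RR > 1.5 requirement
  discards most chance-significant pairs.
* **Estimator recovery** — four disjoint three-code modules planted at
  within-layer RR 4.0 (membership 0.2, baseline 0.05) in layers 3–6;
  the pooled CMH RR of the 12 planted pairs, over two independent
  registries, should fall in [3.4, 4.6] (±15%) for ≥ 90% of pairs.
* **Bifurcation recovery** — one branch family: two trunk conditions
  (G47 sleep disorder, I10 hypertension) occurring at ages 20–29 only,
  and two 12-code complication clusters with onset at ages 30–39
  (metabolic/digestive vs neuro/sensory/mechanical), progression 0.95,
  per-diagnosis in-hospital mortality 0.02 vs 0.002 (10×). The
  restriction of trunk support to the split layer and of complications
  to the branch layer makes the trunk nodes the branch nodes' dominant
  interlayer parents after per-target normalization — the regime in
  which local fitness growth attaches the shared trunk to both
  branches; the mortality differential lives in the small-m regime
  where M is monotone. The noise field uses 16 background codes at
  prevalences 0.12–0.25, frequent enough that association estimates
  rest on large exposure denominators. A run
  counts as recovered when some flagged critical event's pair matches
  the two planted branch trajectories at Jaccard ≥ 0.5 on both sides;
  the study reports the recovery rate over 20 seeded runs.
* **Community benchmarks** — disjoint cliques must return exactly; the
  overlapping benchmark plants a chain of ten-node communities sharing
  one node (internal edge probability 0.95) plus random external edges
  realizing a target mixing ≤ 0.2, scoring mean best-match Jaccard.
  Smaller or looser instances sit at the resolution limit of fitness
  maximization with a = 1, where the union of two overlapping cliques
  outscores its parts (see Limitations).

The acceptance script (`scripts/acceptance.py`) re-runs all of the
above from scratch plus the vocabulary/stratification arithmetic, an
independent-oracle check of the pooled RR (statsmodels), the exhaustive
set-algebra oracle of the pair classifier, and the mortality formula's
closed-form values, deriving every seed from `--seed`.

## Numerical choices

* Tie-breaks: lexicographic by node id everywhere in detection;
  community growth counts improvements only above 1e-12.
* Normalization conservation is asserted to 1e-9 at build time.
* Pooled RR with zero denominator → +inf, flagged, capped at 100 for
  the link weight; 0/0 → NaN, never emitted.
* Stay length floor: same-day stays count as 1 day (configurable 0).
* Degenerate inputs: an empty post-filter network raises; an empty
  follower set reports missing means, never 0; diagnoses without
  carriers are excluded from M with a warning.

## Known limitations

* **Resolution limit of a = 1 fitness.** Unions of weakly separated
  communities can have near-maximal fitness; on synthetic networks the
  detector sometimes returns a merged super-community instead of (or in
  addition to) two overlapping branches, and occasionally attaches the
  shared trunk to only one branch. This is inherent to single-scale
  local fitness maximization; the resolution parameter a would expose
  the hierarchy but is held at the natural value 1.
* **Normalization inflates lone links.** A node's only incoming link of
  a type gets weight 1.0 however weak its evidence; on sparse synthetic
  networks, spurious links between distant layers (estimated on small
  boundary-age exposure populations) occasionally recruit noise nodes
  into communities, which can also break the earliest-layer overlap
  condition of the diverging definition.
* **Interlayer ratios carry no significance test**, mirroring the
  method definition; their noise scales with 1/exposed count.
* **In-hospital mortality only**; out-of-hospital deaths are invisible,
  and M's exactly-one-death form is interpretable only for small m.
* The T1/T2 frame split can only estimate layer transitions that are
  demographically reachable within 12 calendar years; links between
  distant layers rest on narrow birth-cohort slivers.
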