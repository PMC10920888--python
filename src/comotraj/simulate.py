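"""Synthetic hospital-registry generator with planted trajectory structure.

The generator emulates the schema of a national in-patient registry
(pseudonymous patient id, sex, 5-year age band, admission/release dates,
release type, primary + secondary 3-digit ICD-10 codes, calendar years
1997–2014) and plants known comorbidity/trajectory structure so every
downstream stage has ground truth:

* Each patient has a birth year (uniform ages 0–79 at the start of the
  observation window in 2003) that fixes which ten-year age-group layers
  they traverse during 2003–2014, keeping layer membership and the
  T1/T2 frame split mutually consistent.
* *Background* diagnoses are independent Bernoulli draws per (code,
  layer) at configured baseline prevalences.
* A :class:`PlantedModule` is a latent patient class: members express the
  module's codes of a layer with a probability calibrated (given the
  membership rate and the background baseline) so that the single-stratum
  relative risk of any two module codes equals ``within_rr`` in
  expectation.  Module activity progresses to the next module layer with
  ``progression_prob``, which plants interlayer (temporal) structure.
* Branch families (``branch_of``) share their lowest-layer codes but send
  each member down exactly one branch — a planted *diverging* trajectory
  pair, optionally with differential in-hospital mortality to plant a
  critical event.
* Deaths are drawn from ``mortality_by_code`` on the patient's last stay
  of the age group and truncate the record; no post-death stays exist.

All randomness flows through one ``numpy`` generator seeded from the
config, so a fixed seed reproduces the registry bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
from scipy.optimize import brentq

from .records import HospitalStay
from .trajectories import Trajectory

OBSERVATION = (2003, 2014)
WASHOUT = (1997, 2002)
#: out-of-range encounter placeholder used when a hospitalized patient has
#: no in-range diagnosis (maps to the sentinel code at ingestion)
ENCOUNTER_CODE = "Z76"


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configs."""


@dataclass(frozen=True)
class PlantedModule:
    """One planted disease module / trajectory.

    ``codes_by_layer`` maps age-group layers to the module's codes there;
    ``within_rr`` is the target single-stratum relative risk between any
    two module codes of the same layer; ``progression_prob`` the chance an
    active member carries the module into its next layer; ``branch_of``
    links diverging branches that share their lowest-layer codes.
    """

    module_id: str
    codes_by_layer: dict
    within_rr: float = 4.0
    progression_prob: float = 0.6
    membership_prob: float = 0.15
    mortality_by_code: dict = field(default_factory=dict)
    branch_of: str | None = None

    def __post_init__(self):
        if self.within_rr <= 1:
            raise ConfigError(f"{self.module_id}: within_rr must exceed 1")
        for p in (self.progression_prob, self.membership_prob):
            if not 0 <= p <= 1:
                raise ConfigError(f"{self.module_id}: probability outside [0,1]")
        for m in self.mortality_by_code.values():
            if not 0 <= m <= 1:
                raise ConfigError(f"{self.module_id}: mortality outside [0,1]")

    @property
    def layers(self):
        return tuple(sorted(self.codes_by_layer))

    def trajectory(self) -> Trajectory:
        tuples = frozenset(
            (code, layer)
            for layer, codes in self.codes_by_layer.items()
            for code in codes
        )
        return Trajectory(id=self.module_id, tuples=tuples)


@dataclass(frozen=True)
class SimulationConfig:
    """Registry-level simulation parameters.

    ``background_prevalence`` maps ``(code, age_group)`` to the baseline
    per-decade probability of the diagnosis among hospitalized patients.
    Stay counts per patient and age group are ``1 + Poisson(stay_rate)``;
    stay lengths are log-normal in days.  The wash-out years are left
    empty for cohort patients; ``washout_contamination`` adds that
    fraction of extra patients with a pre-2003 stay to exercise the
    wash-out filter.
    """

    n_patients: int = 20_000
    male_fraction: float = 0.5
    background_prevalence: dict = field(default_factory=dict)
    modules: tuple = ()
    #: chance a background condition carried in one age group persists
    #: into the next (chronic-disease recurrence); the innovation rate is
    #: chosen so each layer's marginal stays at background_prevalence
    persistence_prob: float = 0.4
    stay_rate: float = 0.7
    stay_days_mu: float = 1.0
    stay_days_sigma: float = 0.8
    washout_contamination: float = 0.05
    ensure_hospitalization: bool = True
    seed: int = 0

    def __post_init__(self):
        for (code, layer), p in self.background_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence of {code}@{layer} outside [0,1]")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction outside [0,1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: module memberships and calibrated probabilities."""

    modules: tuple
    memberships: dict  # module_id -> tuple of patient ids
    expression_probs: dict  # (module_id, layer) -> member expression prob
    config: SimulationConfig


# ---------------------------------------------------------------------------
# calibration

def _single_stratum_rr(m, pi, p0):
    """Expected single-stratum RR between two module codes.

    Conditional independence given membership: P(code|member) = m,
    P(code|non-member) = p0, membership rate pi.
    """
    p = pi * m + (1 - pi) * p0
    pij = pi * m * m + (1 - pi) * p0 * p0
    if p >= 1 or p <= 0:
        return np.nan
    return (pij / p) / ((p - pij) / (1 - p))


def solve_expression_prob(pi, p0, target_rr):
    """Member expression probability m with single-stratum RR = target.

    Raises :class:`ConfigError` when the target is unattainable even at
    m = 1 (the module would need joint probability above 1).
    """
    if not 0 < pi < 1:
        raise ConfigError(f"membership rate {pi} must be in (0,1)")
    hi = _single_stratum_rr(1.0 - 1e-9, pi, p0)
    if not np.isfinite(hi) or hi < target_rr:
        raise ConfigError(
            f"within_rr {target_rr} infeasible at membership {pi}, baseline {p0}"
        )
    return brentq(
        lambda m: _single_stratum_rr(m, pi, p0) - target_rr, p0 + 1e-9, 1 - 1e-9,
        xtol=1e-12,
    )


def _families(modules):
    """Group modules into branch families keyed by the root module id."""
    by_id = {m.module_id: m for m in modules}
    fams: dict[str, list] = {}
    for m in modules:
        root = m.module_id
        seen = set()
        while by_id[root].branch_of is not None:
            if root in seen:
                raise ConfigError("branch_of cycle")
            seen.add(root)
            parent = by_id[root].branch_of
            if parent not in by_id:
                raise ConfigError(f"unknown parent module {parent!r}")
            root = parent
        fams.setdefault(root, []).append(m)
    return fams


def _calibrate(cfg: SimulationConfig):
    """Solve the member expression probability for every (module, layer).

    Within a branch family, codes listed identically by several branches
    (the shared low-layer codes) are expressed by members of *any* branch,
    so their calibration uses the summed active-membership rate.
    """
    probs = {}
    fams = _families(cfg.modules)
    for root, members in sorted(fams.items()):
        for mod in members:
            for k, layer in enumerate(mod.layers):
                codes = frozenset(mod.codes_by_layer[layer])
                # active membership rate of every branch planting the same
                # codes in this layer (chain-discounted by progression)
                pi = 0.0
                for other in members:
                    if frozenset(other.codes_by_layer.get(layer, ())) == codes:
                        kk = other.layers.index(layer)
                        pi += other.membership_prob * other.progression_prob ** kk
                p0s = {
                    cfg.background_prevalence.get((c, layer), 0.02)
                    for c in codes
                }
                if len(p0s) > 1:
                    raise ConfigError(
                        f"{mod.module_id}@{layer}: module codes need a common "
                        f"baseline prevalence, got {sorted(p0s)}"
                    )
                probs[(mod.module_id, layer)] = solve_expression_prob(
                    pi, p0s.pop(), mod.within_rr
                )
    return probs


# ---------------------------------------------------------------------------
# simulation

def _layer_years(birth, layer):
    lo = birth + 10 * (layer - 1)
    return lo, lo + 9


def simulate_cohort(cfg: SimulationConfig):
    """Generate a synthetic registry.

    Returns ``(stays, ground_truth)``: the stay list (sorted by patient,
    layer, admission date) and the planted structure.
    """
    if cfg.modules:
        # module codes planted twice outside a branch family are ambiguous
        fams = _families(cfg.modules)
        owner = {}
        for root, members in fams.items():
            for mod in members:
                for layer, codes in mod.codes_by_layer.items():
                    for c in codes:
                        if owner.setdefault((c, layer), root) != root:
                            raise ConfigError(
                                f"code {c}@{layer} planted by two families"
                            )
    expression = _calibrate(cfg) if cfg.modules else {}

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    pid = np.array([f"P{i:06d}" for i in range(n)])
    birth = 2003 - rng.integers(0, 80, size=n)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")

    # family membership and branch assignment (exclusive within a family)
    member = {m.module_id: np.zeros(n, dtype=bool) for m in cfg.modules}
    for root, members in sorted(_families(cfg.modules).items()):
        probs = np.array([m.membership_prob for m in members])
        if probs.sum() > 1:
            raise ConfigError(f"family {root}: membership probs sum above 1")
        u = rng.random(n)
        edges = np.concatenate([[0.0], np.cumsum(probs)])
        for k, mod in enumerate(members):
            member[mod.module_id] = (edges[k] <= u) & (u < edges[k + 1])

    # progression chains: is the module active for this member in layer?
    active = {}
    for mod in sorted(cfg.modules, key=lambda m: m.module_id):
        alive_chain = member[mod.module_id].copy()
        for k, layer in enumerate(mod.layers):
            if k > 0:
                alive_chain &= rng.random(n) < mod.progression_prob
            active[(mod.module_id, layer)] = alive_chain.copy()

    mort = {}
    for mod in cfg.modules:
        for (code, layer), m in mod.mortality_by_code.items():
            mort[(code, layer)] = m

    bg_by_layer: dict[int, list] = {layer: [] for layer in range(1, 9)}
    for (code, layer), p in cfg.background_prevalence.items():
        bg_by_layer[layer].append((code, p))
    for layer in bg_by_layer:
        bg_by_layer[layer].sort()

    stays: list[HospitalStay] = []
    alive = np.ones(n, dtype=bool)
    rho = cfg.persistence_prob
    latent_prev: dict = {}  # code -> (background presence, marginal) last layer
    for layer in range(1, 9):
        ylo = np.maximum(birth + 10 * (layer - 1), OBSERVATION[0])
        yhi = np.minimum(birth + 10 * layer - 1, OBSERVATION[1])
        visited = (ylo <= yhi) & alive

        def bg_draw(code, p):
            """Background latent state: persistence from the previous
            layer plus an innovation rate keeping the marginal at p.
            Prevalence 0 is absorbing: the code cannot occur there."""
            if p == 0:
                return np.zeros(n, dtype=bool), 0.0
            prev = latent_prev.get(code)
            if prev is None or rho == 0:
                return rng.random(n) < p, p
            prev_f, prev_p = prev
            keep = prev_f & (rng.random(n) < rho)
            q = max(0.0, 1 - (1 - p) / (1 - rho * prev_p))
            f = keep | (rng.random(n) < q)
            marginal = 1 - (1 - q) * (1 - rho * prev_p)
            return f, marginal

        # background latent state for every code of this layer's universe
        layer_codes = [c for c, _ in bg_by_layer[layer]]
        layer_p = dict(bg_by_layer[layer])
        for mod in sorted(cfg.modules, key=lambda m: m.module_id):
            for code in sorted(mod.codes_by_layer.get(layer, ())):
                if code not in layer_p:
                    layer_codes.append(code)
                    layer_p[code] = cfg.background_prevalence.get(
                        (code, layer), 0.02)
        latent_now = {}
        for code in layer_codes:
            latent_now[code] = bg_draw(code, layer_p[code])

        # observed presence: module expression overrides the background
        # latent for active members (keeps the pairwise RR calibration
        # exact); everyone else shows the background state
        codes = list(layer_codes)
        flags = [latent_now[c][0].copy() for c in codes]
        pos = {c: k for k, c in enumerate(codes)}
        for mod in sorted(cfg.modules, key=lambda m: m.module_id):
            if layer not in mod.codes_by_layer:
                continue
            act = active[(mod.module_id, layer)]
            m_expr = expression[(mod.module_id, layer)]
            for code in sorted(mod.codes_by_layer[layer]):
                expr = rng.random(n) < m_expr
                flags[pos[code]] = np.where(act, expr, flags[pos[code]])
        latent_prev = latent_now
        F = np.column_stack(flags) if flags else np.zeros((n, 0), dtype=bool)
        F[~visited] = False

        # in-hospital death probability from the planted mortalities
        p_death = np.zeros(n)
        if mort:
            surv = np.ones(n)
            for k, code in enumerate(codes):
                m = mort.get((code, layer))
                if m:
                    surv *= np.where(F[:, k], 1 - m, 1.0)
            p_death = 1 - surv
        dies = (rng.random(n) < p_death) & visited

        n_stays = 1 + rng.poisson(cfg.stay_rate, size=n)

        codes_arr = np.array(codes) if codes else np.empty(0, dtype=object)
        for i in np.nonzero(visited)[0]:
            pat_codes = [str(c) for c in codes_arr[F[i]]]
            if not pat_codes:
                if not cfg.ensure_hospitalization:
                    continue
                pat_codes = [ENCOUNTER_CODE]
            k_stays = int(n_stays[i])
            years = ylo[i] + (rng.random(k_stays) * (yhi[i] - ylo[i] + 1)).astype(int)
            days0 = (rng.random(k_stays) * 364).astype(int)
            lengths = np.round(
                rng.lognormal(cfg.stay_days_mu, cfg.stay_days_sigma, k_stays)
            ).astype(int)
            order = np.lexsort((days0, years))
            age = np.asarray(years) - birth[i]
            for j, k in enumerate(order):
                adm = date(int(years[k]), 1, 1) + timedelta(days=int(days0[k]))
                rel = adm + timedelta(days=int(lengths[k]))
                primary = pat_codes[j % len(pat_codes)]
                diag = (primary, *[c for c in pat_codes if c != primary])
                stays.append(HospitalStay(
                    patient_id=str(pid[i]),
                    sex=str(sex[i]),
                    age_band=int(age[k] // 5 * 5),
                    admission_date=adm,
                    release_date=rel,
                    release_type="death" if (dies[i] and j == len(order) - 1)
                    else "discharge",
                    diagnoses=diag,
                ))
        alive &= ~dies

    # contaminant patients with a wash-out stay (removed by the filter)
    n_extra = int(round(cfg.washout_contamination * n))
    for i in range(n_extra):
        wyear = WASHOUT[0] + int(rng.random() * (WASHOUT[1] - WASHOUT[0] + 1))
        oyear = OBSERVATION[0] + int(rng.random() * 11)
        age_w = int(rng.random() * 60)
        code = bg_by_layer[1][0][0] if bg_by_layer[1] else "J18"
        for year, age in ((wyear, max(age_w - (oyear - wyear), 0)), (oyear, age_w)):
            adm = date(year, 6, 1)
            stays.append(HospitalStay(
                patient_id=f"W{i:06d}",
                sex="male" if rng.random() < cfg.male_fraction else "female",
                age_band=min(age // 5 * 5, 95),
                admission_date=adm,
                release_date=adm + timedelta(days=2),
                release_type="discharge",
                diagnoses=(code,),
            ))

    stays.sort(key=lambda s: (s.patient_id, s.admission_date, s.diagnoses))
    gt = GroundTruth(
        modules=tuple(cfg.modules),
        memberships={
            mid: tuple(pid[np.nonzero(flag)[0]]) for mid, flag in member.items()
        },
        expression_probs=expression,
        config=cfg,
    )
    return stays, gt


# ---------------------------------------------------------------------------
# ground truth accessors

def ground_truth_trajectories(gt: GroundTruth):
    """Render every planted module as a trajectory of (code, layer) tuples."""
    return [m.trajectory() for m in gt.modules]


def planted_pairs(gt: GroundTruth):
    """All distinct within-layer module code pairs ``(i, j, layer)``."""
    pairs = set()
    for mod in gt.modules:
        for layer, codes in mod.codes_by_layer.items():
            cs = sorted(codes)
            for a in range(len(cs)):
                for b in range(a + 1, len(cs)):
                    pairs.add((cs[a], cs[b], layer))
    return sorted(pairs)


def write_ground_truth(gt: GroundTruth, path):
    payload = {
        "modules": [
            {
                "module_id": m.module_id,
                "codes_by_layer": {str(k): sorted(v)
                                   for k, v in m.codes_by_layer.items()},
                "within_rr": m.within_rr,
                "progression_prob": m.progression_prob,
                "membership_prob": m.membership_prob,
                "branch_of": m.branch_of,
            }
            for m in gt.modules
        ],
        "memberships": {k: list(v) for k, v in gt.memberships.items()},
        "trajectories": [
            {"id": t.id, "tuples": sorted(map(list, t.tuples))}
            for t in ground_truth_trajectories(gt)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# canonical study configurations

#: common hospital diagnoses used as independent background noise
BACKGROUND_CODES = (
    "A09", "B34", "C44", "D50", "E11", "E66", "E78", "F32", "F41", "G40",
    "G47", "H25", "I10", "I25", "I48", "J18", "J44", "K29", "K80", "L40",
    "M17", "M54", "N18", "N39",
)
_PREVALENCE_CYCLE = (0.06, 0.10, 0.15, 0.20, 0.25)


def default_background(codes=BACKGROUND_CODES, layers=range(1, 9)):
    """Baseline prevalences: each code at one of five fixed levels, the
    same in every layer (hospitalized-population scale)."""
    return {
        (code, layer): _PREVALENCE_CYCLE[k % len(_PREVALENCE_CYCLE)]
        for k, code in enumerate(codes)
        for layer in layers
    }


def branch_pair_modules(
    shared_codes=("G47", "I10"),
    split_layer=3,
    branch_a=("E11", "E16", "E66", "E78", "E79", "E88",
              "I25", "K75", "K76", "K80", "K86", "K90"),
    branch_b=("F03", "G20", "G21", "G25", "G30", "H66",
              "H81", "H83", "H90", "K46", "M41", "M45"),
    within_rr=4.0,
    progression_prob=0.9,
    membership_prob=0.15,
    mortality_a=0.02,
    mortality_b=0.002,
    baseline=0.03,
):
    """A planted diverging pair: two branches sharing their trunk codes
    at the split layer and accumulating different complication clusters
    one age group later, with 10x differential per-diagnosis mortality
    between the branches (the planted critical event).

    The trunk conditions occur only at the split layer and the branch
    complications only at the next layer (first-onset diagnoses), so the
    trunk nodes are the branch nodes' only systematic interlayer
    parents in the built network.  Returns ``(modules,
    extra_background)``.
    """
    nxt = split_layer + 1
    mod_a = PlantedModule(
        module_id="branchA",
        codes_by_layer={split_layer: tuple(shared_codes), nxt: tuple(branch_a)},
        within_rr=within_rr,
        progression_prob=progression_prob,
        membership_prob=membership_prob,
        mortality_by_code={(c, nxt): mortality_a for c in branch_a},
    )
    mod_b = PlantedModule(
        module_id="branchB",
        codes_by_layer={split_layer: tuple(shared_codes), nxt: tuple(branch_b)},
        within_rr=within_rr,
        progression_prob=progression_prob,
        membership_prob=membership_prob,
        mortality_by_code={(c, nxt): mortality_b for c in branch_b},
        branch_of="branchA",
    )
    extra = {}
    for c in shared_codes:
        for layer in range(1, 9):
            extra[(c, layer)] = baseline if layer == split_layer else 0.0
    for c in (*branch_a, *branch_b):
        for layer in range(1, 9):
            extra[(c, layer)] = baseline if layer == nxt else 0.0
    return (mod_a, mod_b), extra


def rr_recovery_modules():
    """Twelve planted within-layer pairs for estimator-recovery studies:
    four latent classes of three codes each, one per mid-life layer."""
    blocks = {
        "metabolic": (3, ("E11", "E66", "E78")),
        "cardio": (4, ("I10", "I25", "I48")),
        "digestive": (5, ("K29", "K80", "N18")),
        "mental": (6, ("F32", "F41", "G40")),
    }
    modules, extra = [], {}
    for mid, (layer, codes) in blocks.items():
        modules.append(PlantedModule(
            module_id=mid,
            codes_by_layer={layer: codes},
            within_rr=4.0,
            membership_prob=0.2,
        ))
        for c in codes:
            for lay in range(1, 9):
                extra[(c, lay)] = 0.05
    return tuple(modules), extra


def study_config(n_patients=20_000, modules=(), seed=0, **kwargs):
    """Canonical simulation config: default background plus any planted
    modules (module-code baselines override the background defaults).

    Recovery experiments analyze one sex stratum, so their canonical
    configs set ``male_fraction=1.0`` with ``n_patients`` the size of the
    analyzed stratum.
    """
    background = default_background()
    extra = kwargs.pop("extra_background", {})
    background.update(extra)
    return SimulationConfig(
        n_patients=n_patients,
        modules=tuple(modules),
        background_prevalence=background,
        seed=seed,
        **kwargs,
    )
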