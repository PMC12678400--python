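"""Synthetic paired PD cohorts with planted, rule-defined subtypes.

No generative model is published for the clinical cohorts this pipeline is
designed around, so every distributional choice here is an explicit stand-in
(see docs/methods.md). The generator emulates the *summary* statistics the
analysis assumes: ~70 ordinal 0-4 MDS-UPDRS items dominated by Normal/Slight
ratings, a 0-15 geriatric depression score, gender, a ~2:1 late:early onset
imbalance, per-feature missingness, an older validation cohort, and planted
conjunction-of-conditions subtypes correlated with onset class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, FeatureInfo
from .rules import GT, LE, RuleCondition

# Clinical item names follow the MDS-UPDRS question codes of the training
# cohort's data dictionary. Parts 1-2 (non-motor / motor experiences of daily
# living), Part 3 (motor examination), Part 4 (motor complications).
_NP1 = ["NP1COG", "NP1HALL", "NP1DPRS", "NP1ANXS", "NP1APAT", "NP1DDS", "NP1SLPN",
        "NP1SLPD", "NP1PAIN", "NP1URN", "NP1CNST", "NP1LTHD", "NP1FATG"]
_NP2 = ["NP2SPCH", "NP2SALV", "NP2SWAL", "NP2EAT", "NP2DRES", "NP2HYGN", "NP2HWRT",
        "NP2HOBB", "NP2TURN", "NP2TRMR", "NP2RISE", "NP2WALK", "NP2FREZ"]
_NP3 = ["NP3SPCH", "NP3FACXP", "NP3RIGN", "NP3RIGRU", "NP3RIGLU", "NP3RIGRL",
        "NP3RIGLL", "NP3FTAPR", "NP3FTAPL", "NP3HMOVR", "NP3HMOVL", "NP3PRSPR",
        "NP3PRSPL", "NP3TTAPR", "NP3TTAPL", "NP3LGAGR", "NP3LGAGL", "NP3RISNG",
        "NP3GAIT", "NP3FRZGT", "NP3PSTBL", "NP3POSTR", "NP3BRADY", "NP3PTRMR",
        "NP3PTRML", "NP3KTRMR", "NP3KTRML", "NP3RTARU", "NP3RTALU", "NP3RTARL",
        "NP3RTALL", "NP3RTALJ", "NP3RTCON"]
_NP4 = ["NP4WDYSK", "NP4DYSKI", "NP4OFF", "NP4FLCTI", "NP4FLCTX", "NP4DYSTN"]
UPDRS_ITEMS = _NP1 + _NP2 + _NP3 + _NP4


def truncated_geometric(q: float, k: int) -> tuple[float, ...]:
    """Probabilities proportional to ``q**i`` over ``{0, ..., k-1}``.

    With q < 1 the mass concentrates on the low categories, mirroring the
    predominance of Normal/Slight ratings on clinical scales.
    """
    w = np.power(q, np.arange(k))
    return tuple(w / w.sum())


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical feature of the generator schema.

    ``kind`` is one of ``ordinal0_4``, ``ordinal0_5``, ``integer0_15``,
    ``binary``; ``probs`` are the baseline category probabilities over the
    feature's integer support starting at 0.
    """

    name: str
    kind: str
    probs: tuple[float, ...]

    _SUPPORT = {"ordinal0_4": 5, "ordinal0_5": 6, "integer0_15": 16, "binary": 2}

    def __post_init__(self) -> None:
        if self.kind not in self._SUPPORT:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        k = self._SUPPORT[self.kind]
        probs = np.asarray(self.probs, dtype=float)
        if len(probs) != k:
            raise ValueError(f"{self.name}: expected {k} category probabilities")
        if np.any(probs < 0) or np.any(probs > 1) or not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"{self.name}: category probabilities must sum to 1")

    @property
    def n_categories(self) -> int:
        return self._SUPPORT[self.kind]

    @property
    def info(self) -> FeatureInfo:
        kind = {"binary": "binary", "integer0_15": "integer"}.get(self.kind, "ordinal")
        return FeatureInfo(kind, 0, self.n_categories - 1)


@dataclass(frozen=True)
class PlantedSubtype:
    """Ground-truth subtype planted into a synthetic cohort.

    Members are forced (with probability ``adherence`` per patient) to
    satisfy every rule condition; ``onset_skew`` is the fraction of members
    drawn as late onset.
    """

    name: str
    conditions: tuple[RuleCondition, ...]
    prevalence: float
    onset_skew: float
    adherence: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.onset_skew <= 1:
            raise ValueError("onset_skew must be in [0, 1]")
        if not 0.5 < self.adherence <= 1:
            raise ValueError("adherence must be in (0.5, 1]")


def default_feature_schema() -> list[FeatureSpec]:
    """65 UPDRS ordinal items, dyskinesia flags, H&Y stage, GDS-15, gender."""
    base = truncated_geometric(0.45, 5)
    schema = [FeatureSpec(name, "ordinal0_4", base) for name in UPDRS_ITEMS]
    schema.append(FeatureSpec("DYSKPRES", "binary", (0.8, 0.2)))
    schema.append(FeatureSpec("DYSKIRAT", "binary", (0.9, 0.1)))
    # H&Y stage concentrates on stage 2, per the training cohort's profile.
    schema.append(FeatureSpec("NHY", "ordinal0_5",
                              (0.02, 0.13, 0.56, 0.15, 0.10, 0.04)))
    schema.append(FeatureSpec("GDS15SCORE", "integer0_15", truncated_geometric(0.8, 16)))
    schema.append(FeatureSpec("gender", "binary", (0.46, 0.54)))  # 1 = male
    return schema


def default_missingness() -> dict[str, float]:
    """Mostly sub-1% missingness with a few notably incomplete items."""
    rates = {spec.name: 0.005 for spec in default_feature_schema()}
    rates["DYSKIRAT"] = 0.095
    rates["GDS15SCORE"] = 0.058
    rates["NP4FLCTX"] = 0.20  # exercises the >15%-missing feature drop
    rates["gender"] = 0.0
    return rates


def default_planted_subtypes() -> list[PlantedSubtype]:
    """Two well-separated ground-truth subtypes, one early- one late-skewed."""
    return [
        PlantedSubtype(
            name="planted_early",
            conditions=(RuleCondition("NP3GAIT", GT, 3.5),
                        RuleCondition("NP2TRMR", GT, 3.5)),
            prevalence=0.10,
            onset_skew=0.05,
        ),
        PlantedSubtype(
            name="planted_late",
            conditions=(RuleCondition("NP3RIGN", GT, 3.5),
                        RuleCondition("NP1CNST", GT, 3.5)),
            prevalence=0.10,
            onset_skew=0.95,
        ),
    ]


@dataclass
class GeneratorConfig:
    """Full description of a synthetic cohort pair.

    Defaults emulate the training cohort's published summary statistics:
    a ~2:1 late:early onset split, onset ages near 42.6 +/- 10.5 (early) and
    58 +/- 10.5 (late) years truncated to the class ranges, an assessment
    offset giving a mean disease duration of ~8 years, and a validation
    cohort shifted ~5 years older.
    """

    n_patients: int = 400
    onset_mix: float = 2 / 3  # fraction late onset
    onset_age_params: dict = field(
        default_factory=lambda: {"early": (42.6, 10.5), "late": (58.0, 10.5)})
    assessment_offset_params: tuple[float, float] = (8.0, 6.5)
    feature_schema: list[FeatureSpec] = field(default_factory=default_feature_schema)
    planted_subtypes: list[PlantedSubtype] = field(default_factory=default_planted_subtypes)
    missingness: dict[str, float] = field(default_factory=default_missingness)
    demographic_shift_years: float = 5.0
    seed: int = 0

    # class ranges for rounded ages of onset
    EARLY_RANGE = (22, 49)
    LATE_RANGE = (51, 95)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0 < self.onset_mix < 1:
            raise ValueError("onset_mix must be in (0, 1)")
        total_prev = sum(p.prevalence for p in self.planted_subtypes)
        if total_prev > 1:
            raise ValueError("planted subtype prevalences sum above 1")
        for name, rate in self.missingness.items():
            if not 0 <= rate <= 0.3:
                raise ValueError(f"missingness for {name!r} outside [0, 0.3]")
        schema = {spec.name: spec for spec in self.feature_schema}
        for planted in self.planted_subtypes:
            for cond in planted.conditions:
                spec = schema.get(cond.feature)
                if spec is None:
                    raise ValueError(
                        f"planted rule condition '{cond}' references a feature "
                        "absent from the schema")
                if not _allowed_categories(spec, cond).any():
                    raise ValueError(
                        f"infeasible planted rule condition '{cond}': no value "
                        f"of {cond.feature} (range 0..{spec.n_categories - 1}) "
                        "satisfies it")
        for cls, (mean, _sd) in self.onset_age_params.items():
            lo, hi = self.EARLY_RANGE if cls == "early" else self.LATE_RANGE
            if not lo <= mean <= hi:
                raise ValueError(f"{cls} onset mean {mean} outside [{lo}, {hi}]")


def _allowed_categories(spec: FeatureSpec, cond: RuleCondition) -> np.ndarray:
    values = np.arange(spec.n_categories, dtype=float)
    return cond.evaluate(values)


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    cdf = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").astype(float)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, n: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.random(n))


def generate_cohort(config: GeneratorConfig, *, age_shift: float = 0.0,
                    _seed_seq: np.random.SeedSequence | None = None,
                    id_prefix: str = "P") -> Cohort:
    """Draw one cohort under ``config``.

    Planted members are allocated first by prevalence, their onset class by
    ``onset_skew``, and their features forced to satisfy the rule with
    per-patient probability ``adherence``; remaining patients draw from the
    baseline distributions. Missingness is then injected independently per
    cell. ``age_shift`` is added to onset and assessment ages before
    rounding (used for the validation cohort of a pair).
    """
    config.validate()
    seq = _seed_seq if _seed_seq is not None else np.random.SeedSequence(config.seed)
    # independent substreams per stage so adding a stage never perturbs others
    s_member, s_onset, s_age, s_feat, s_force, s_miss = seq.spawn(6)
    n = config.n_patients

    ids = np.array([f"{id_prefix}{i:05d}" for i in range(1, n + 1)])
    rng_member = np.random.default_rng(s_member)
    perm = rng_member.permutation(n)
    membership = np.full(n, -1)  # index into planted_subtypes, -1 = background
    cursor = 0
    for j, planted in enumerate(config.planted_subtypes):
        size = int(round(planted.prevalence * n))
        membership[perm[cursor:cursor + size]] = j
        cursor += size

    # onset class: 1 = late
    rng_onset = np.random.default_rng(s_onset)
    u = rng_onset.random(n)
    late = np.where(membership < 0, u < config.onset_mix, False)
    for j, planted in enumerate(config.planted_subtypes):
        sel = membership == j
        late[sel] = u[sel] < planted.onset_skew

    # ages
    rng_age = np.random.default_rng(s_age)
    e_mean, e_sd = config.onset_age_params["early"]
    l_mean, l_sd = config.onset_age_params["late"]
    lo_e, hi_e = config.EARLY_RANGE
    lo_l, hi_l = config.LATE_RANGE
    ao = np.empty(n)
    ao[~late] = _truncnorm(rng_age, e_mean, e_sd, lo_e - 0.49, hi_e + 0.49, int((~late).sum()))
    ao[late] = _truncnorm(rng_age, l_mean, l_sd, lo_l - 0.49, hi_l + 0.49, int(late.sum()))
    off_mean, off_sd = config.assessment_offset_params
    offset = _truncnorm(rng_age, off_mean, off_sd, 0.0, 45.0, n)
    ageonset = np.round(ao + age_shift)
    assessment_age = np.round(ao + offset + age_shift)

    # baseline features
    rng_feat = np.random.default_rng(s_feat)
    columns: dict[str, np.ndarray] = {}
    for spec in config.feature_schema:
        columns[spec.name] = _draw_categorical(
            rng_feat, np.asarray(spec.probs), n)

    # force planted rule conditions
    rng_force = np.random.default_rng(s_force)
    schema = {spec.name: spec for spec in config.feature_schema}
    for j, planted in enumerate(config.planted_subtypes):
        members = np.flatnonzero(membership == j)
        adheres = members[rng_force.random(len(members)) < planted.adherence]
        for cond in planted.conditions:
            spec = schema[cond.feature]
            allowed = _allowed_categories(spec, cond)
            probs = np.asarray(spec.probs) * allowed
            probs = probs / probs.sum()
            columns[cond.feature][adheres] = _draw_categorical(
                rng_force, probs, len(adheres))

    # missingness
    rng_miss = np.random.default_rng(s_miss)
    for name, rate in config.missingness.items():
        if rate <= 0 or name not in columns:
            continue
        mask = rng_miss.random(n) < rate
        columns[name][mask] = np.nan

    frame = pd.DataFrame({"patient_id": ids,
                          "ageonset": ageonset,
                          "assessment_age": assessment_age,
                          **columns})
    dictionary = {spec.name: spec.info for spec in config.feature_schema}
    dictionary["ageonset"] = FeatureInfo("numeric", 0, 120)
    dictionary["assessment_age"] = FeatureInfo("numeric", 0, 120)
    planted_sets = {
        planted.name: frozenset(ids[membership == j])
        for j, planted in enumerate(config.planted_subtypes)
    }
    return Cohort(frame=frame, dictionary=dictionary, planted=planted_sets or None)


def generate_paired_cohorts(config: GeneratorConfig) -> tuple[Cohort, Cohort]:
    """Training cohort plus a demographically shifted validation cohort.

    Both cohorts share the feature schema and planted rules; the validation
    cohort draws from an independent seed stream and has onset and
    assessment ages shifted older by ``demographic_shift_years``.
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    train_seq, valid_seq = seq.spawn(2)
    train = generate_cohort(config, _seed_seq=train_seq, id_prefix="T")
    valid = generate_cohort(config, age_shift=config.demographic_shift_years,
                            _seed_seq=valid_seq, id_prefix="V")
    return train, valid
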