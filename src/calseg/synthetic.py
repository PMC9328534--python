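"""Synthetic calendar records with the structure the analysis assumes.

The generator emulates the study conditions of the Burundi analysis:
six archetype sequences (an all-nonuse "quiet" calendar, two
family-building profiles with two 9-month pregnancy spells at different
timings, and post-pregnancy adopters of short-term modern, long-acting,
and traditional methods), the published mixture weights
(41.5 / 24.9 / 18.1 / 7.6 / 5.6 / 2.3 percent), per-month state noise,
spell-boundary jitter, categorical covariates tied to membership
through a logistic model, and a stratified two-stage survey design with
lognormal weights.

Two membership modes:

* ``mixture`` - cluster labels drawn directly from the mixture weights;
  covariates independent of membership. The marginal cluster shares are
  then exactly the configured weights.
* ``binary`` - membership in one focal cluster is Bernoulli through a
  logistic link on the covariates, so the membership model has an
  exactly-true coefficient vector for recovery experiments; non-members
  are spread over the remaining archetypes by renormalized weights.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .calendar_io import CalendarRecord
from .states import LAPM, NONE, PREG, SEQ_LENGTH, STM, TRAD

#: Calendar characters emitted per state (all map back through the
#: default CodeMap): non-use '0', injectable '3', implant 'N',
#: rhythm '8'; pregnancy spells end with a birth 'B' preceded by 'P's.
_STATE_CHAR = {NONE: "0", STM: "3", LAPM: "N", TRAD: "8", PREG: "P"}

#: Width of the emitted calendar column block (DHS convention).
CALENDAR_WIDTH = 80


@dataclass(frozen=True)
class Archetype:
    """A representative sequence given as ordered (state, months) spells."""

    name: str
    spells: tuple  # of (state, duration)

    def __post_init__(self) -> None:
        total = sum(d for _, d in self.spells)
        if total != SEQ_LENGTH or any(d <= 0 for _, d in self.spells):
            raise ValueError(
                f"{self.name}: spell durations must be positive and sum to "
                f"{SEQ_LENGTH}, got {self.spells}"
            )

    def sequence(self) -> np.ndarray:
        return np.concatenate(
            [np.full(d, s, dtype=np.int8) for s, d in self.spells]
        )


def default_archetypes() -> tuple[Archetype, ...]:
    """The six default archetypes.

    States and their ordering follow the published cluster descriptions;
    the exact spell boundaries are this package's defaults and are fully
    configurable (the source figures print no numeric boundaries).
    """
    return (
        Archetype("Quiet Calendar", ((NONE, 59),)),
        Archetype("Family Builder 1",
                  ((NONE, 4), (PREG, 9), (NONE, 17), (PREG, 9), (NONE, 20))),
        Archetype("Family Builder 2",
                  ((NONE, 16), (PREG, 9), (NONE, 14), (PREG, 9), (NONE, 11))),
        Archetype("Modern Mother",
                  ((NONE, 10), (PREG, 9), (NONE, 5), (STM, 35))),
        Archetype("Consistently Covered Mother",
                  ((NONE, 10), (PREG, 9), (NONE, 5), (LAPM, 35))),
        Archetype("Traditional Mother",
                  ((NONE, 10), (PREG, 9), (NONE, 5), (TRAD, 35))),
    )


#: Published cluster distribution (percent / 100).
DEFAULT_MIXTURE_WEIGHTS = (0.415, 0.249, 0.181, 0.076, 0.056, 0.023)


def default_covariates() -> dict:
    """Marginal distributions of the default categorical covariates.

    Education and contraceptive-knowledge marginals follow the published
    sample profile; the fertility-desire marginal is a package default
    (the source tables print intentions, not desires).
    """
    return {
        "education": {"none": 0.448, "primary": 0.368, "secondary+": 0.184},
        "knowledge": {"low": 0.292, "medium": 0.266, "high": 0.442},
        "fertility_desire": {"soon": 0.25, "after2": 0.35,
                             "unsure": 0.15, "nomore": 0.25},
    }


@dataclass(frozen=True)
class EffectSpec:
    """Membership-model coefficients linking covariates to cluster labels.

    ``mode="mixture"``: labels come straight from the mixture weights
    (``coefficients`` ignored). ``mode="binary"``: membership in
    ``focal_cluster`` is Bernoulli(expit(alpha + x'beta)) with betas
    from ``coefficients`` - a dict {(covariate, level): log-odds-ratio}
    relative to each covariate's first listed level - and alpha solved
    so the marginal membership probability equals ``target_share``.
    """

    mode: str = "mixture"
    focal_cluster: str = "Quiet Calendar"
    target_share: float = 0.415
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("mixture", "binary"):
            raise ValueError(f"unknown effect mode {self.mode!r}")


def quiet_calendar_effects() -> EffectSpec:
    """Binary-mode effects mirroring the published focal-cluster model:
    secondary+ education OR 3.68 (primary 1.10), medium/high
    contraceptive knowledge OR 0.70, fertility desire unsure-of-timing
    OR 4.21 (delay / no-more OR 0.35) - all for the all-nonuse cluster."""
    return EffectSpec(
        mode="binary",
        focal_cluster="Quiet Calendar",
        target_share=0.415,
        coefficients={
            ("education", "primary"): math.log(1.10),
            ("education", "secondary+"): math.log(3.68),
            ("knowledge", "medium"): math.log(0.70),
            ("knowledge", "high"): math.log(0.70),
            ("fertility_desire", "after2"): math.log(0.35),
            ("fertility_desire", "unsure"): math.log(4.21),
            ("fertility_desire", "nomore"): math.log(0.35),
        },
    )


@dataclass(frozen=True)
class GeneratorConfig:
    archetypes: tuple = field(default_factory=default_archetypes)
    mixture_weights: tuple = DEFAULT_MIXTURE_WEIGHTS
    noise_sub_prob: float = 0.03
    jitter_max: int = 2
    n_strata: int = 10
    psus_per_stratum: int = 20
    women_per_psu: int = 50
    weight_cv: float = 0.3
    n_women: int | None = None  # derived from the design when omitted
    covariates: dict = field(default_factory=default_covariates)
    effects: EffectSpec = field(default_factory=EffectSpec)
    interview_cmc: int = 1404  # December 2016
    seed: int = 12345

    def __post_init__(self) -> None:
        problems = []
        if len(self.archetypes) != len(self.mixture_weights):
            problems.append("archetypes and mixture_weights lengths differ")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            problems.append("mixture_weights must sum to 1")
        if any(w < 0 for w in self.mixture_weights):
            problems.append("mixture_weights must be nonnegative")
        if not 0.0 <= self.noise_sub_prob <= 1.0:
            problems.append("noise_sub_prob must lie in [0, 1]")
        if self.jitter_max < 0:
            problems.append("jitter_max must be nonnegative")
        design_n = self.n_strata * self.psus_per_stratum * self.women_per_psu
        if self.n_women is not None and self.n_women != design_n:
            problems.append(
                f"n_women={self.n_women} inconsistent with design product {design_n}"
            )
        for name, dist in self.covariates.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                problems.append(f"covariate {name!r} probabilities must sum to 1")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))
        if self.n_women is None:
            object.__setattr__(self, "n_women", design_n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["archetypes"] = [
            {"name": a.name, "spells": [list(sp) for sp in a.spells]}
            for a in self.archetypes
        ]
        d["mixture_weights"] = list(self.mixture_weights)
        return d


@dataclass
class SyntheticTruth:
    """Recovery-test bookkeeping: true labels and true coefficients."""

    labels: pd.DataFrame            # case_id, cluster (archetype name)
    coefficients: dict | None       # binary mode: term -> true log-OR (+ alpha)
    config: GeneratorConfig


def _solve_alpha(config: GeneratorConfig) -> float:
    """Intercept such that the expected membership share over the
    covariate cell distribution equals the configured target share."""
    spec = config.effects
    cells = [({}, 1.0)]
    for name, dist in config.covariates.items():
        cells = [
            (dict(assign, **{name: level}), p * q)
            for assign, p in cells
            for level, q in dist.items()
        ]
    etas = np.array([
        sum(spec.coefficients.get((n, lv), 0.0) for n, lv in assign.items())
        for assign, _ in cells
    ])
    probs = np.array([p for _, p in cells])

    def share(alpha: float) -> float:
        return float(np.sum(probs / (1.0 + np.exp(-(alpha + etas)))))

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if share(mid) < spec.target_share:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _realize_sequence(archetype: Archetype, rng: np.random.Generator,
                      noise_sub_prob: float, jitter_max: int) -> np.ndarray:
    """Archetype with jittered spell boundaries and per-month noise."""
    sp = list(archetype.spells)
    if jitter_max > 0 and len(sp) > 1:
        bounds = np.cumsum([d for _, d in sp])[:-1]  # internal boundaries
        new_bounds = []
        prev = 0
        for idx, b in enumerate(bounds):
            remaining = len(bounds) - idx - 1
            shift = int(rng.integers(-jitter_max, jitter_max + 1))
            b_new = int(np.clip(b + shift, prev + 1, SEQ_LENGTH - 1 - remaining))
            new_bounds.append(b_new)
            prev = b_new
        cuts = [0] + new_bounds + [SEQ_LENGTH]
        seq = np.concatenate([
            np.full(cuts[i + 1] - cuts[i], sp[i][0], dtype=np.int8)
            for i in range(len(sp))
        ])
    else:
        seq = archetype.sequence().copy()
    if noise_sub_prob > 0:
        flips = rng.random(SEQ_LENGTH) < noise_sub_prob
        if flips.any():
            # uniformly random *other* state
            offsets = rng.integers(1, 5, size=int(flips.sum()))
            seq[flips] = (seq[flips] + offsets) % 5
    return seq


def _calendar_string(seq: np.ndarray) -> str:
    """Emit the DHS-order calendar string: leftmost = most recent month;
    each pregnancy spell ends in a birth code."""
    chars = [_STATE_CHAR[int(s)] for s in seq]
    i = 0
    while i < SEQ_LENGTH:
        if seq[i] == PREG:
            j = i
            while j + 1 < SEQ_LENGTH and seq[j + 1] == PREG:
                j += 1
            chars[j] = "B"  # most recent month of the spell
            i = j + 1
        else:
            i += 1
    chars.reverse()  # month 59 (most recent) first
    return "".join(chars).ljust(CALENDAR_WIDTH)


def generate(config: GeneratorConfig) -> tuple[list[CalendarRecord], SyntheticTruth]:
    """Generate calendar records and the truth sidecar; deterministic
    given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    names = [a.name for a in config.archetypes]
    weights = np.asarray(config.mixture_weights, dtype=np.float64)

    # covariates
    cov_draws: dict[str, np.ndarray] = {}
    for name, dist in config.covariates.items():
        levels = list(dist)
        cov_draws[name] = rng.choice(levels, size=n, p=list(dist.values()))

    # cluster membership
    spec = config.effects
    true_coefs: dict | None = None
    if spec.mode == "binary":
        if spec.focal_cluster not in names:
            raise ValueError(f"focal cluster {spec.focal_cluster!r} not an archetype")
        focal = names.index(spec.focal_cluster)
        alpha = _solve_alpha(config)
        eta = np.full(n, alpha)
        for (cname, level), beta in spec.coefficients.items():
            eta += beta * (cov_draws[cname] == level)
        member = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        rest = np.delete(np.arange(len(names)), focal)
        rest_w = weights[rest] / weights[rest].sum()
        labels = np.where(
            member, focal, rng.choice(rest, size=n, p=rest_w)
        ).astype(int)
        true_coefs = {"alpha": alpha}
        true_coefs.update({f"{c}={lv}": b for (c, lv), b in spec.coefficients.items()})
    else:
        labels = rng.choice(len(names), size=n, p=weights)

    # survey design: PSUs cycled round-robin, strata blocks of PSUs
    n_psus = config.n_strata * config.psus_per_stratum
    psu = np.arange(n) % n_psus
    stratum = psu // config.psus_per_stratum
    sigma2 = math.log(1.0 + config.weight_cv**2)
    w = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)

    # ages: 15-44 completed years at the start of the window
    start_cmc = config.interview_cmc - (SEQ_LENGTH - 1)
    age_years = rng.integers(15, 45, size=n)
    age_months = rng.integers(0, 12, size=n)
    birth_cmc = start_cmc - (age_years * 12 + age_months)

    records: list[CalendarRecord] = []
    for i in range(n):
        seq = _realize_sequence(
            config.archetypes[labels[i]], rng,
            config.noise_sub_prob, config.jitter_max,
        )
        records.append(
            CalendarRecord(
                case_id=f"W{i:06d}",
                calendar=_calendar_string(seq),
                interview_cmc=config.interview_cmc,
                birth_cmc=int(birth_cmc[i]),
                weight=float(w[i]),
                psu=int(psu[i]),
                stratum=int(stratum[i]),
                covariates={name: cov_draws[name][i] for name in cov_draws},
            )
        )
    truth = SyntheticTruth(
        labels=pd.DataFrame(
            {"case_id": [r.case_id for r in records],
             "cluster": [names[l] for l in labels]}
        ),
        coefficients=true_coefs,
        config=config,
    )
    return records, truth


def truth_assignment_accuracy(truth_labels, solution_labels) -> float:
    """Chance-adjusted agreement (adjusted Rand index) between the true
    and recovered partitions: 1 iff identical, ~0 under random labels."""
    truth_labels = np.asarray(truth_labels)
    solution_labels = np.asarray(solution_labels)
    if truth_labels.shape != solution_labels.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(truth_labels, solution_labels))
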