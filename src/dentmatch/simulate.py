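"""Synthetic paired past/recent dentition cohorts.

Generates the kind of data the identification pipeline assumes: for each
individual an antemortem (AM) baseline dentition is drawn from per-state
priors, an imaging interval is sampled from a truncated normal matching the
reference population (mean 2,197.5 d, sd 1,934.7 d, support [1, 7,732] d),
and the postmortem (PM) dentition is produced by forward-simulating each
tooth independently as a discrete-time Markov chain on the treatment graph,
one step per started 100-day period.  Because the chain only moves along
graph edges, a generated PM state is always reachable from its AM state —
true pairs never incur the discrepancy penalty unless detector noise is
switched on.  Optional noise replaces each state with a confusable one with
probability (1 - recall) of its detection category, mimicking an imperfect
radiograph detector.

All randomness flows through one ``numpy.random.Generator`` derived from
the config seed; identical configs give byte-identical cohorts.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .dentition import (
    FDI_POSITIONS,
    Dentition,
    ToothState,
    TransitionGraph,
    default_transition_graph,
)
from .intervals import IntervalDataset
from .matching import DentitionRecord

__all__ = [
    "NoiseParams",
    "CohortConfig",
    "sample_am_dentition",
    "sample_interval_days",
    "forward_simulate",
    "inject_detection_noise",
    "generate_cohort",
    "make_step_dataset",
]

#: Hazard time unit: one simulation step per started 100-day period, the
#: same discretization the interval regression uses.
STEP_DAYS = 100

# Detector recall per state category; natural teeth, prostheses, treated
# root canals and implants follow the reference detector's measured recall.
# Missing positions and pontics have no measured category and default to
# perfect detection.
DEFAULT_RECALL: dict[ToothState, float] = {
    ToothState.NATURAL: 0.996,
    ToothState.PROSTHESIS: 0.843,
    ToothState.ROOT_CANAL: 0.892,
    ToothState.IMPLANT: 0.981,
    ToothState.MISSING: 1.0,
    ToothState.PONTIC: 1.0,
}

# What a missed detection is read as instead.  Natural vs restored is the
# classic hard call; a missed root-canal trace reads as an untreated or
# merely restored tooth; a missed implant fixture with a crown reads as a
# bridge pontic.
DEFAULT_CONFUSIONS: dict[ToothState, tuple[ToothState, ...]] = {
    ToothState.NATURAL: (ToothState.PROSTHESIS,),
    ToothState.PROSTHESIS: (ToothState.NATURAL,),
    ToothState.ROOT_CANAL: (ToothState.NATURAL, ToothState.PROSTHESIS),
    ToothState.IMPLANT: (ToothState.PONTIC,),
    ToothState.MISSING: (),
    ToothState.PONTIC: (),
}

# Baseline state mix of a 20-49-year-old adult dentition: mostly natural
# teeth, a modest restored fraction, few root canals, little tooth loss.
DEFAULT_PRIORS: dict[ToothState, float] = {
    ToothState.NATURAL: 0.80,
    ToothState.PROSTHESIS: 0.12,
    ToothState.ROOT_CANAL: 0.04,
    ToothState.MISSING: 0.02,
    ToothState.PONTIC: 0.01,
    ToothState.IMPLANT: 0.01,
}

# Per-edge probability of one treatment step per 100 days of elapsed time.
# Escalation out of NATURAL dominates; movement within the missing/pontic/
# implant cluster is slower.
DEFAULT_HAZARDS: dict[tuple[ToothState, ToothState], float] = {
    (ToothState.NATURAL, ToothState.PROSTHESIS): 0.0030,
    (ToothState.NATURAL, ToothState.ROOT_CANAL): 0.0010,
    (ToothState.NATURAL, ToothState.MISSING): 0.0005,
    (ToothState.PROSTHESIS, ToothState.ROOT_CANAL): 0.0020,
    (ToothState.PROSTHESIS, ToothState.MISSING): 0.0010,
    (ToothState.ROOT_CANAL, ToothState.MISSING): 0.0020,
    (ToothState.MISSING, ToothState.IMPLANT): 0.0030,
    (ToothState.MISSING, ToothState.PONTIC): 0.0015,
    (ToothState.PONTIC, ToothState.MISSING): 0.0005,
    (ToothState.PONTIC, ToothState.IMPLANT): 0.0005,
    (ToothState.IMPLANT, ToothState.MISSING): 0.0003,
    (ToothState.IMPLANT, ToothState.PONTIC): 0.0001,
}


@dataclass(frozen=True)
class NoiseParams:
    """Detector-noise model: per-category recall and confusion targets."""

    recall: Mapping[ToothState, float] = field(
        default_factory=lambda: dict(DEFAULT_RECALL)
    )
    confusions: Mapping[ToothState, tuple[ToothState, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONFUSIONS)
    )

    def __post_init__(self) -> None:
        for s in ToothState:
            r = self.recall.get(s, 1.0)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"recall for {s} must be in [0, 1], got {r}")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one reproducible paired cohort.

    The defaults reproduce the reference study population's bookkeeping:
    1,029 individuals (54.8% women, ages 20-49), imaging intervals from a
    truncated normal with mean 2,197.5 and sd 1,934.7 days on [1, 7,732].
    ``female_hazard_multiplier`` scales all transition hazards for women
    (< 1 means slower dentition drift, hence easier identification); it is
    a synthetic device for producing a sex effect, not a biological claim.
    """

    n_individuals: int = 1029
    sex_ratio_female: float = 564 / 1029
    age_range: tuple[int, int] = (20, 49)
    interval_mean: float = 2197.5
    interval_sd: float = 1934.7
    interval_min: int = 1
    interval_max: int = 7732
    baseline_priors: Mapping[ToothState, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )
    transition_hazards: Mapping[tuple[ToothState, ToothState], float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    female_hazard_multiplier: float = 0.5
    noise: NoiseParams | None = None
    noise_on_am: bool = False
    study_start: datetime.date = datetime.date(2000, 1, 1)
    study_end: datetime.date = datetime.date(2020, 11, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must be in [0, 1]")
        total = sum(self.baseline_priors.get(s, 0.0) for s in ToothState)
        if any(p < 0 for p in self.baseline_priors.values()) or not math.isclose(
            total, 1.0, abs_tol=1e-9
        ):
            raise ValueError("baseline_priors must be non-negative and sum to 1")
        for (a, b), h in self.transition_hazards.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hazard for {a}->{b} must be in [0, 1]")
        if self.interval_min < 1 or self.interval_min > self.interval_max:
            raise ValueError("need 1 <= interval_min <= interval_max")

    def validate_against_graph(self, graph: TransitionGraph) -> None:
        """Reject hazards on pairs that are not edges of ``graph``."""
        bad = [
            (a.value, b.value)
            for (a, b) in self.transition_hazards
            if not graph.has_edge(a, b)
        ]
        if bad:
            raise ValueError(f"hazards reference non-edges: {bad}")


def _prior_vector(config: CohortConfig) -> np.ndarray:
    return np.array(
        [config.baseline_priors.get(s, 0.0) for s in ToothState], dtype=float
    )


def sample_am_dentition(
    config: CohortConfig, rng: np.random.Generator
) -> Dentition:
    """Draw one baseline dentition, positions i.i.d. from the state priors."""
    states = list(ToothState)
    draws = rng.choice(len(states), size=len(FDI_POSITIONS), p=_prior_vector(config))
    return Dentition.from_codes([states[i] for i in draws])


@lru_cache(maxsize=32)
def _interval_law(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[str, float, float]:
    """Moment-matched interval law on [lo, hi] with the given mean and sd.

    Returns ``("mixture", weight, exp_scale)`` for a truncated-exponential +
    uniform mixture, or ``("truncnorm", loc, scale)`` for a truncated
    normal.  The mixture covers the high-dispersion regime (sd comparable
    to the mean, as in the reference interval summary 2,197.5 +/- 1,934.7
    days) that no truncated normal on the same support can reach; the
    truncated normal covers ordinary bell-shaped targets.  Parameters are
    solved so the *post-truncation* moments equal the targets.
    """
    m2, v2 = (lo + hi) / 2.0, (hi - lo) ** 2 / 12.0

    def mixture_residual(params):
        w, scale = params
        b = (hi - lo) / scale
        m1, v1 = stats.truncexpon.stats(b, loc=lo, scale=scale, moments="mv")
        mix_mean = w * m1 + (1 - w) * m2
        mix_ex2 = w * (v1 + m1**2) + (1 - w) * (v2 + m2**2)
        return [mix_mean - mean, mix_ex2 - (sd * sd + mean * mean)]

    with np.errstate(all="ignore"):
        try:
            sol, _info, ier, _msg = optimize.fsolve(
                mixture_residual, x0=[0.8, max(sd, 1.0)], full_output=True
            )
            w, scale = float(sol[0]), float(sol[1])
            if ier == 1 and 0.0 <= w <= 1.0 and scale > 0:
                return ("mixture", w, scale)
        except Exception:
            pass

        def truncnorm_residual(params):
            loc, scale = params
            a, b = (lo - loc) / scale, (hi - loc) / scale
            m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
            return [m - mean, np.sqrt(v) - sd]

        try:
            sol, _info, ier, _msg = optimize.fsolve(
                truncnorm_residual, x0=[mean, sd], full_output=True
            )
            loc, scale = float(sol[0]), float(sol[1])
            if ier == 1 and scale > 0:
                return ("truncnorm", loc, scale)
        except Exception:
            pass
    # last resort: truncated normal parameterized directly by the targets
    return ("truncnorm", float(mean), float(sd))


def sample_interval_days(
    config: CohortConfig, rng: np.random.Generator, size: int | None = None
):
    """Imaging intervals in whole days, moment-matched to the config.

    The sampling law is solved once per (mean, sd, min, max) so that the
    realized interval distribution reproduces the configured mean and sd
    after truncation to ``[interval_min, interval_max]``.
    """
    n = 1 if size is None else int(size)
    lo, hi = float(config.interval_min), float(config.interval_max)
    if hi == lo:
        days = np.full(n, config.interval_min, dtype=np.int64)
        return int(days[0]) if size is None else days
    law = _interval_law(float(config.interval_mean), float(config.interval_sd), lo, hi)
    if law[0] == "mixture":
        _, w, scale = law
        b = (hi - lo) / scale
        exp_draws = stats.truncexpon.rvs(
            b, loc=lo, scale=scale, size=n, random_state=rng
        )
        uni_draws = rng.uniform(lo, hi, size=n)
        draws = np.where(rng.random(n) < w, exp_draws, uni_draws)
    else:
        _, loc, scale = law
        a, b = (lo - loc) / scale, (hi - loc) / scale
        draws = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    days = np.clip(np.rint(draws), lo, hi).astype(np.int64)
    return int(days[0]) if size is None else days


def _step_matrix(
    config: CohortConfig, graph: TransitionGraph, hazard_scale: float
) -> np.ndarray:
    """One-step (per 100 days) transition matrix over the six states."""
    states = list(ToothState)
    idx = {s: i for i, s in enumerate(states)}
    mat = np.zeros((len(states), len(states)), dtype=float)
    for (a, b), h in config.transition_hazards.items():
        mat[idx[a], idx[b]] = h * hazard_scale
    row_sums = mat.sum(axis=1)
    if (row_sums > 1.0 + 1e-12).any():
        raise ValueError("scaled hazards out of a state exceed probability 1")
    np.fill_diagonal(mat, 1.0 - row_sums)
    return mat


def forward_simulate(
    am: Dentition,
    interval_days: int,
    config: CohortConfig,
    rng: np.random.Generator,
    graph: TransitionGraph | None = None,
    hazard_scale: float = 1.0,
) -> Dentition:
    """Evolve a dentition over ``interval_days`` along the treatment graph.

    Each position runs an independent discrete-time chain for
    ``ceil(interval_days / 100)`` steps (so any positive interval gets at
    least one step); per step the tooth follows edge (a, b) with
    probability ``hazard * hazard_scale`` and otherwise stays.  The output
    state is therefore always reachable from the input state.
    """
    if interval_days < 0:
        raise ValueError("interval_days must be non-negative")
    graph = graph or default_transition_graph()
    config.validate_against_graph(graph)
    mat = _step_matrix(config, graph, hazard_scale)
    states = list(ToothState)
    idx = {s: i for i, s in enumerate(states)}
    n_steps = max(1, math.ceil(interval_days / STEP_DAYS)) if interval_days else 0
    current = np.array([idx[s] for s in am.codes()], dtype=np.int64)
    for _ in range(n_steps):
        # vectorized one categorical draw per position
        u = rng.random(current.size)
        cum = np.cumsum(mat[current], axis=1)
        current = (u[:, None] > cum).sum(axis=1)
    return Dentition.from_codes([states[i] for i in current])


def inject_detection_noise(
    d: Dentition, noise: NoiseParams, rng: np.random.Generator
) -> Dentition:
    """Corrupt each position with probability (1 - recall of its state).

    A corrupted state is replaced by a uniform draw from its confusable
    states; states with no confusion target are left unchanged.
    """
    out = []
    for state in d.codes():
        r = noise.recall.get(state, 1.0)
        targets = noise.confusions.get(state, ())
        if targets and rng.random() > r:
            out.append(targets[int(rng.integers(len(targets)))])
        else:
            out.append(state)
    return Dentition.from_codes(out)


def generate_cohort(
    config: CohortConfig, graph: TransitionGraph | None = None
) -> tuple[list[DentitionRecord], dict]:
    """Draw a full paired cohort plus its ground-truth manifest.

    Returns ``(records, manifest)``: two records (one AM, one PM) per
    individual, ids ``I0000``..., AM dates placed inside the study window
    so the PM date fits, and a manifest with the true pairing, per-pair
    interval, sex, and the per-edge count of true state transitions (for
    parameter-recovery checks).
    """
    graph = graph or default_transition_graph()
    config.validate_against_graph(graph)
    rng = np.random.default_rng(config.seed)
    width = len(str(max(config.n_individuals - 1, 1)))
    records: list[DentitionRecord] = []
    manifest_pairs = []
    transition_counts: dict[tuple[str, str], int] = {}
    window_days = (config.study_end - config.study_start).days
    intervals = sample_interval_days(config, rng, size=config.n_individuals)
    sexes = np.where(
        rng.random(config.n_individuals) < config.sex_ratio_female, "F", "M"
    )
    ages = rng.integers(
        config.age_range[0], config.age_range[1] + 1, size=config.n_individuals
    )
    for i in range(config.n_individuals):
        ind_id = f"I{i:0{width}d}"
        interval = int(intervals[i])
        sex = str(sexes[i])
        scale = config.female_hazard_multiplier if sex == "F" else 1.0
        am_dent = sample_am_dentition(config, rng)
        pm_dent = forward_simulate(
            am_dent, interval, config, rng, graph=graph, hazard_scale=scale
        )
        for a, b in zip(am_dent.codes(), pm_dent.codes()):
            if a != b:
                key = (a.value, b.value)
                transition_counts[key] = transition_counts.get(key, 0) + 1
        am_obs, pm_obs = am_dent, pm_dent
        if config.noise is not None:
            pm_obs = inject_detection_noise(pm_dent, config.noise, rng)
            if config.noise_on_am:
                am_obs = inject_detection_noise(am_dent, config.noise, rng)
        latest_start = max(window_days - interval, 0)
        am_offset = int(rng.integers(0, latest_start + 1))
        am_date = config.study_start + datetime.timedelta(days=am_offset)
        pm_date = am_date + datetime.timedelta(days=interval)
        records.append(
            DentitionRecord(ind_id, sex, am_date, "AM", am_obs)
        )
        records.append(
            DentitionRecord(ind_id, sex, pm_date, "PM", pm_obs)
        )
        manifest_pairs.append(
            {
                "individual_id": ind_id,
                "sex": sex,
                "age": int(ages[i]),
                "interval_days": interval,
                "am_date": am_date.isoformat(),
                "pm_date": pm_date.isoformat(),
            }
        )
    manifest = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "pairs": manifest_pairs,
        "true_transition_counts": {
            f"{a}->{b}": n for (a, b), n in sorted(transition_counts.items())
        },
    }
    return records, manifest


def make_step_dataset(
    n_pairs: int,
    step_at_days: int,
    effect: float,
    noise_sd: float,
    rng: np.random.Generator,
    base_similarity: float = 0.95,
    unit_days: int = 100,
    window: tuple[float, float] = (1.5, 4.5),
) -> IntervalDataset:
    """Similarity data with one known change-point, for sweep validation.

    Mean similarity is ``base_similarity`` for intervals below
    ``step_at_days`` and drops by ``effect`` at and above it; i.i.d.
    Gaussian noise of ``noise_sd`` is added.  Intervals are sampled
    uniformly on ``[step - window[0]*unit, step + window[1]*unit)``.

    The window is an identifiability design, not a model of the study
    population: a dense, bounded support keeps every threshold bin well
    populated (coefficient differences at thresholds with near-empty dummy
    groups are pure noise and would swamp the step), and placing more mass
    above the change-point than below makes the coefficient jump at the
    threshold leaving the change-point strictly larger than the jump
    entering it, so the section starting at ``step_at_days`` is the unique
    deterministic trend-change argmax.
    """
    if step_at_days % unit_days != 0:
        raise ValueError("step_at_days must be a multiple of unit_days")
    lo = int(step_at_days - window[0] * unit_days)
    hi = int(step_at_days + window[1] * unit_days)
    if lo < 1:
        raise ValueError("window extends below 1 day")
    days = rng.integers(lo, hi, size=n_pairs)
    mean = np.where(days >= step_at_days, base_similarity - effect, base_similarity)
    sim = mean + rng.normal(0.0, noise_sd, size=n_pairs)
    return IntervalDataset(days, sim)


def drift_free(config: CohortConfig) -> CohortConfig:
    """A copy of ``config`` with all hazards and noise switched off."""
    return replace(
        config,
        transition_hazards={k: 0.0 for k in config.transition_hazards},
        noise=None,
    )
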