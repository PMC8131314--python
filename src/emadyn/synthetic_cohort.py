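"""Synthetic EMA data with known ground truth.

The generator produces the statistical structure the downstream analysis
assumes so that every stage is testable end to end:

* a latent standardized lag-1 VAR shared by the continuous variables, with
  an overnight break — the latent state restarts each morning from its
  stationary distribution, so no lag-1 dependence crosses a night;
* slow sinusoidal trends, a time-of-day (circadian) component, an additive
  weekend shift, and an exogenous categorical context variable with
  per-level offsets, all on the observed VAS (0-100) scale;
* prompt compliance that decays over the study (answer probability
  ``p0 * daily_decay**day``), independent of the latent state by default
  (MCAR), with an optional state-dependent (MAR) mode.

Observed values are clipped to [0, 100]; the clipped fraction is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_discrete_lyapunov

from .ema_design import (
    PromptSchedule,
    StudyDesign,
    build_prompt_schedule,
    format_clock,
    parse_clock,
    validate_design,
)
from .errors import EmadynError, InvalidDesignError, ParameterError

__all__ = [
    "CompliancePlan",
    "ContextSpec",
    "DgpParameters",
    "EmaDataset",
    "default_dgp",
    "null_dgp",
    "innovations_for_unit_variance",
    "simulate_subject",
    "apply_missingness",
    "simulate_cohort",
    "dgp_to_dict",
    "dgp_from_dict",
    "save_dgp",
    "load_dgp",
    "write_dataset_csv",
    "read_dataset_csv",
]


@dataclass(frozen=True)
class CompliancePlan:
    """Answer probability p0 * daily_decay**day on study day ``day``.

    The default (p0=0.52, daily_decay=0.993) puts the long-run answer
    fraction in the low-forties-percent regime typical of adolescent EMA
    over ~7 weeks.  ``state_slope`` > 0 makes answering less likely when
    the first model variable (canonically fatigue) is high, on the logit
    scale per latent SD — an MAR mode for sensitivity checks.
    """

    p0: float = 0.52
    daily_decay: float = 0.993
    state_slope: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.p0 <= 1.0:
            raise ParameterError(f"compliance p0 must be in (0, 1], got {self.p0}")
        if not 0.0 < self.daily_decay <= 1.0:
            raise ParameterError(f"daily_decay must be in (0, 1], got {self.daily_decay}")

    def expected_answer_fraction(self, n_days: int) -> float:
        """Closed-form mean answer fraction over the study period."""
        d = np.arange(n_days)
        return float(self.p0 * np.mean(self.daily_decay ** d))


@dataclass(frozen=True)
class ContextSpec:
    """Exogenous categorical context, i.i.d. across occasions.

    ``offsets`` has one row per level and one column per continuous
    variable: additive VAS-unit shifts while the context is in that level.
    """

    item_id: str = "location"
    level_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    offsets: tuple[tuple[float, ...], ...] = ()

    @property
    def n_levels(self) -> int:
        return len(self.level_probs)

    def offsets_array(self, k: int) -> np.ndarray:
        if not self.offsets:
            return np.zeros((self.n_levels, k))
        arr = np.asarray(self.offsets, dtype=float)
        if arr.shape != (self.n_levels, k):
            raise ParameterError(
                f"context offsets shape {arr.shape} != ({self.n_levels}, {k})"
            )
        return arr

    def validate(self) -> None:
        p = np.asarray(self.level_probs, dtype=float)
        if p.ndim != 1 or len(p) < 2 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ParameterError("context level_probs must be >=2 nonnegative values summing to 1")


@dataclass(frozen=True)
class DgpParameters:
    """Ground truth for one simulated subject.

    ``lag_matrix`` is on the standardized latent scale: entry [i, j] is the
    effect of variable j at occasion t-1 on variable i at t.  ``scale``
    converts latent SD units to VAS units.
    """

    variables: tuple[str, ...]
    lag_matrix: np.ndarray
    innovation_cov: np.ndarray
    baseline: np.ndarray
    scale: np.ndarray
    trend_amplitude: np.ndarray
    trend_period_days: np.ndarray
    circadian_amplitude: np.ndarray
    circadian_peak: np.ndarray  # minutes since midnight
    weekend_shift: np.ndarray
    context: ContextSpec | None = None
    compliance: CompliancePlan = field(default_factory=CompliancePlan)

    @property
    def k(self) -> int:
        return len(self.variables)

    def validate(self) -> None:
        k = self.k
        if k < 1 or k > 6:
            raise ParameterError(f"between 1 and 6 variables supported, got {k}")
        phi = np.asarray(self.lag_matrix, dtype=float)
        if phi.shape != (k, k):
            raise ParameterError(f"lag_matrix shape {phi.shape} != ({k}, {k})")
        rho = np.max(np.abs(np.linalg.eigvals(phi)))
        if rho >= 1.0:
            raise ParameterError(
                f"lag_matrix is non-stationary: spectral radius {rho:.4f} >= 1"
            )
        sig = np.asarray(self.innovation_cov, dtype=float)
        if sig.shape != (k, k) or not np.allclose(sig, sig.T, atol=1e-10):
            raise ParameterError("innovation_cov must be a symmetric KxK matrix")
        try:
            np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            raise ParameterError("innovation_cov is not positive definite") from None
        for name in ("baseline", "scale", "trend_amplitude", "trend_period_days",
                     "circadian_amplitude", "circadian_peak", "weekend_shift"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ParameterError(f"{name} must have one entry per variable")
        if ((self.baseline < 0) | (self.baseline > 100)).any():
            raise ParameterError("baseline means must lie in [0, 100]")
        if (np.asarray(self.trend_period_days) <= 0).any():
            raise ParameterError("trend_period_days must be positive")
        if self.context is not None:
            self.context.validate()
            self.context.offsets_array(k)
        self.compliance.validate()

    def stationary_cov(self) -> np.ndarray:
        """Solve V = Phi V Phi' + Sigma for the within-day stationary covariance."""
        return solve_discrete_lyapunov(
            np.asarray(self.lag_matrix, float), np.asarray(self.innovation_cov, float)
        )


def _vec(x, k: int) -> np.ndarray:
    return np.full(k, float(x)) if np.isscalar(x) else np.asarray(x, dtype=float)


def make_dgp(
    variables,
    lag_matrix,
    innovation_cov=None,
    baseline=50.0,
    scale=10.0,
    trend_amplitude=0.0,
    trend_period_days=14.0,
    circadian_amplitude=0.0,
    circadian_peak="17:00",
    weekend_shift=0.0,
    context: ContextSpec | None = None,
    compliance: CompliancePlan | None = None,
) -> DgpParameters:
    """Convenience constructor with scalar broadcasting and validation."""
    variables = tuple(variables)
    k = len(variables)
    phi = np.asarray(lag_matrix, dtype=float)
    if innovation_cov is None:
        innovation_cov = innovations_for_unit_variance(phi)
    if isinstance(circadian_peak, str):
        circadian_peak = parse_clock(circadian_peak)
    dgp = DgpParameters(
        variables=variables,
        lag_matrix=phi,
        innovation_cov=np.asarray(innovation_cov, dtype=float),
        baseline=_vec(baseline, k),
        scale=_vec(scale, k),
        trend_amplitude=_vec(trend_amplitude, k),
        trend_period_days=_vec(trend_period_days, k),
        circadian_amplitude=_vec(circadian_amplitude, k),
        circadian_peak=_vec(circadian_peak, k),
        weekend_shift=_vec(weekend_shift, k),
        context=context,
        compliance=compliance if compliance is not None else CompliancePlan(),
    )
    dgp.validate()
    return dgp


def innovations_for_unit_variance(phi: np.ndarray, stationary_corr: np.ndarray | None = None) -> np.ndarray:
    """Innovation covariance that makes the stationary covariance equal
    ``stationary_corr`` (default: identity — unit variances, no
    contemporaneous correlation): Sigma = V - Phi V Phi'.

    With unit stationary variances the lag-matrix entries are standardized
    coefficients, so generator effect sizes line up with the estimator's
    standardized-beta scale.
    """
    phi = np.asarray(phi, dtype=float)
    v = np.eye(phi.shape[0]) if stationary_corr is None else np.asarray(stationary_corr, float)
    sigma = v - phi @ v @ phi.T
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ParameterError(
            "lag_matrix too strong for the requested stationary covariance "
            "(implied innovation covariance not positive definite)"
        ) from None
    return sigma


def null_dgp(variables=("fatigue", "worry"), **kwargs) -> DgpParameters:
    """White-noise DGP: no lagged or contemporaneous structure, no trend,
    circadian or weekend effects."""
    k = len(variables)
    return make_dgp(variables, np.zeros((k, k)), np.eye(k), **kwargs)


def default_dgp() -> DgpParameters:
    """Default study-conditions DGP: three coupled variables.

    Cross-lags (0.2-0.4 standardized) straddle the relevance-filter
    threshold; fatigue and worry innovations correlate 0.3; realistic
    trend / circadian / weekend structure on the VAS scale.
    """
    variables = ("fatigue", "worry", "physical_activity")
    phi = np.array(
        [
            [0.30, 0.30, -0.20],  # fatigue <- fatigue, worry, physical_activity
            [0.00, 0.30, 0.00],
            [0.00, 0.00, 0.20],
        ]
    )
    v0 = np.eye(3)
    v0[0, 1] = v0[1, 0] = 0.3  # contemporaneous fatigue-worry coupling
    context = ContextSpec(
        item_id="location",
        level_probs=(0.5, 0.3, 0.2),  # home, school, elsewhere
        offsets=((0.0, 0.0, 0.0), (8.0, 5.0, 0.0), (4.0, 0.0, 5.0)),
    )
    return make_dgp(
        variables,
        phi,
        innovations_for_unit_variance(phi, v0),
        baseline=np.array([55.0, 45.0, 40.0]),
        scale=10.0,
        trend_amplitude=np.array([8.0, 5.0, 4.0]),
        trend_period_days=np.array([21.0, 14.0, 28.0]),
        circadian_amplitude=np.array([10.0, 4.0, 6.0]),
        circadian_peak=np.array([parse_clock("21:00"), parse_clock("22:00"), parse_clock("15:00")], dtype=float),
        weekend_shift=np.array([-5.0, -4.0, 6.0]),
        context=context,
        compliance=CompliancePlan(),
    )


@dataclass
class EmaDataset:
    """Answered-prompt records plus the full schedule they came from."""

    subject_id: str
    design: StudyDesign
    schedule: PromptSchedule
    records: pd.DataFrame  # columns: day_index, clock_time, item_id, value
    answered_mask: np.ndarray
    latent: np.ndarray | None = None  # (n_occasions, K) standardized states
    clipped_fraction: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_sent(self) -> int:
        return len(self.schedule)

    @property
    def n_answered(self) -> int:
        return int(self.answered_mask.sum())

    def fully_answered(self) -> bool:
        return bool(self.answered_mask.all())


RECORD_COLUMNS = ["day_index", "clock_time", "item_id", "value"]


def simulate_subject(design: StudyDesign, dgp: DgpParameters, seed) -> EmaDataset:
    """Simulate one subject's fully-answered EMA dataset.

    Identical seed -> identical dataset.  Every DGP variable must exist in
    the design as a VAS item; the context variable (if any) as a
    categorical item with matching level count.
    """
    violations = validate_design(design)
    if violations:
        raise InvalidDesignError("; ".join(violations))
    dgp.validate()
    for v in dgp.variables:
        try:
            it = design.item(v)
        except KeyError:
            raise InvalidDesignError(f"DGP variable {v!r} is not an item in the design") from None
        if it.scale != "vas":
            raise InvalidDesignError(f"DGP variable {v!r} must be a VAS item")
    if dgp.context is not None:
        try:
            it = design.item(dgp.context.item_id)
        except KeyError:
            raise InvalidDesignError(
                f"context item {dgp.context.item_id!r} is not in the design"
            ) from None
        if it.scale != "categorical" or it.n_categories != dgp.context.n_levels:
            raise InvalidDesignError(
                f"context item {dgp.context.item_id!r} must be categorical with "
                f"{dgp.context.n_levels} levels"
            )

    schedule = build_prompt_schedule(design)
    rng = np.random.default_rng(seed)
    k = dgp.k
    n = len(schedule)
    phi = np.asarray(dgp.lag_matrix, float)
    chol_innov = np.linalg.cholesky(np.asarray(dgp.innovation_cov, float))
    chol_stat = np.linalg.cholesky(dgp.stationary_cov())

    first = schedule.first_of_day
    z = np.empty((n, k))
    state = np.zeros(k)
    for t in range(n):
        if first[t]:
            state = chol_stat @ rng.standard_normal(k)  # overnight reset
        else:
            state = phi @ state + chol_innov @ rng.standard_normal(k)
        z[t] = state

    days = schedule.day_index.astype(float)
    clock = schedule.clock_minutes.astype(float)
    t_days = days + clock / (24 * 60)
    trend = dgp.trend_amplitude * np.sin(
        2 * np.pi * t_days[:, None] / dgp.trend_period_days
    )
    circadian = dgp.circadian_amplitude * np.cos(
        2 * np.pi * (clock[:, None] - dgp.circadian_peak) / (24 * 60)
    )
    weekend = np.outer(schedule.is_weekend.astype(float), dgp.weekend_shift)

    values = dgp.baseline + dgp.scale * z + trend + circadian + weekend

    frames = []
    if dgp.context is not None:
        levels = rng.choice(dgp.context.n_levels, size=n, p=np.asarray(dgp.context.level_probs))
        values = values + dgp.context.offsets_array(k)[levels]
        frames.append(
            pd.DataFrame(
                {
                    "day_index": schedule.day_index,
                    "clock_time": schedule.clock_minutes,
                    "item_id": dgp.context.item_id,
                    "value": levels.astype(float),
                }
            )
        )

    clipped = float(np.mean((values < 0) | (values > 100)))
    values = np.clip(values, 0.0, 100.0)

    for j, var in enumerate(dgp.variables):
        frames.append(
            pd.DataFrame(
                {
                    "day_index": schedule.day_index,
                    "clock_time": schedule.clock_minutes,
                    "item_id": var,
                    "value": values[:, j],
                }
            )
        )
    records = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["day_index", "clock_time", "item_id"], kind="stable")
        .reset_index(drop=True)
    )
    return EmaDataset(
        subject_id=design.subject_id,
        design=design,
        schedule=schedule,
        records=records,
        answered_mask=np.ones(n, dtype=bool),
        latent=z,
        clipped_fraction=clipped,
        meta={"seed": int(np.random.SeedSequence(seed).entropy) if isinstance(seed, int) else None},
    )


def apply_missingness(dataset: EmaDataset, dgp: DgpParameters, seed) -> EmaDataset:
    """Thin the dataset by the compliance model (prompt-level, deterministic
    under seed).  Unanswered prompts leave the records but stay in the
    schedule."""
    plan = dgp.compliance
    plan.validate()
    if not dataset.fully_answered():
        raise EmadynError("apply_missingness expects a fully answered dataset")
    rng = np.random.default_rng(seed)
    days = dataset.schedule.day_index
    p = plan.p0 * plan.daily_decay ** days.astype(float)
    if plan.state_slope != 0.0:
        if dataset.latent is None:
            raise ParameterError("state-dependent missingness needs the latent states")
        z0 = dataset.latent[:, 0]
        logit = np.log(p / (1 - p + 1e-12)) - plan.state_slope * z0
        p = 1.0 / (1.0 + np.exp(-logit))
    answered = rng.random(len(p)) < p

    keep = set(
        (int(d), int(c))
        for d, c, a in zip(dataset.schedule.day_index, dataset.schedule.clock_minutes, answered)
        if a
    )
    rec = dataset.records
    mask = [
        (int(d), int(c)) in keep
        for d, c in zip(rec["day_index"].to_numpy(), rec["clock_time"].to_numpy())
    ]
    return EmaDataset(
        subject_id=dataset.subject_id,
        design=dataset.design,
        schedule=dataset.schedule,
        records=rec.loc[mask].reset_index(drop=True),
        answered_mask=answered,
        latent=dataset.latent,
        clipped_fraction=dataset.clipped_fraction,
        meta={**dataset.meta, "missingness_seed": None},
    )


def _jitter_phi(phi: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian jitter on lag coefficients, rejection-resampled to stay
    comfortably stationary (spectral radius <= 0.95)."""
    for _ in range(1000):
        cand = phi + sd * rng.standard_normal(phi.shape)
        if np.max(np.abs(np.linalg.eigvals(cand))) <= 0.95:
            return cand
    raise ParameterError("could not draw a stationary jittered lag matrix")


def simulate_cohort(
    n_subjects: int,
    design: StudyDesign,
    dgp: DgpParameters,
    master_seed,
    phi_jitter_sd: float = 0.0,
    baseline_jitter_sd: float = 0.0,
    with_missingness: bool = True,
) -> list[EmaDataset]:
    """Simulate a cohort from per-subject seeds derived from master_seed.

    Optional parameter jitter emulates between-person heterogeneity; every
    jittered lag matrix is kept stationary by rejection sampling.
    """
    if n_subjects < 1:
        raise ParameterError(f"n_subjects must be >= 1, got {n_subjects}")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    out = []
    for i, child in enumerate(children):
        sim_seed, miss_seed, jit_seed = child.spawn(3)
        subj_dgp = dgp
        if phi_jitter_sd > 0 or baseline_jitter_sd > 0:
            jrng = np.random.default_rng(jit_seed)
            phi = np.asarray(dgp.lag_matrix, float)
            if phi_jitter_sd > 0:
                phi = _jitter_phi(phi, phi_jitter_sd, jrng)
            base = np.asarray(dgp.baseline, float)
            if baseline_jitter_sd > 0:
                base = np.clip(base + baseline_jitter_sd * jrng.standard_normal(dgp.k), 0, 100)
            subj_dgp = replace(dgp, lag_matrix=phi, baseline=base)
            subj_dgp.validate()
        subj_design = replace(design, subject_id=f"{design.subject_id}-{i + 1:03d}")
        ds = simulate_subject(subj_design, subj_dgp, sim_seed)
        if with_missingness:
            ds = apply_missingness(ds, subj_dgp, miss_seed)
        out.append(ds)
    return out


# --- serialization ----------------------------------------------------------

def dgp_to_dict(dgp: DgpParameters) -> dict:
    d = {
        "variables": list(dgp.variables),
        "lag_matrix": np.asarray(dgp.lag_matrix).tolist(),
        "innovation_cov": np.asarray(dgp.innovation_cov).tolist(),
        "baseline": np.asarray(dgp.baseline).tolist(),
        "scale": np.asarray(dgp.scale).tolist(),
        "trend_amplitude": np.asarray(dgp.trend_amplitude).tolist(),
        "trend_period_days": np.asarray(dgp.trend_period_days).tolist(),
        "circadian_amplitude": np.asarray(dgp.circadian_amplitude).tolist(),
        "circadian_peak": np.asarray(dgp.circadian_peak).tolist(),
        "weekend_shift": np.asarray(dgp.weekend_shift).tolist(),
        "compliance": {
            "p0": dgp.compliance.p0,
            "daily_decay": dgp.compliance.daily_decay,
            "state_slope": dgp.compliance.state_slope,
        },
    }
    if dgp.context is not None:
        d["context"] = {
            "item_id": dgp.context.item_id,
            "level_probs": list(dgp.context.level_probs),
            "offsets": [list(r) for r in dgp.context.offsets] if dgp.context.offsets else [],
        }
    return d


def dgp_from_dict(d: dict) -> DgpParameters:
    context = None
    if "context" in d and d["context"] is not None:
        c = d["context"]
        context = ContextSpec(
            item_id=c["item_id"],
            level_probs=tuple(c["level_probs"]),
            offsets=tuple(tuple(r) for r in c.get("offsets", [])),
        )
    comp = CompliancePlan(**d.get("compliance", {}))
    dgp = DgpParameters(
        variables=tuple(d["variables"]),
        lag_matrix=np.asarray(d["lag_matrix"], float),
        innovation_cov=np.asarray(d["innovation_cov"], float),
        baseline=np.asarray(d["baseline"], float),
        scale=np.asarray(d["scale"], float),
        trend_amplitude=np.asarray(d["trend_amplitude"], float),
        trend_period_days=np.asarray(d["trend_period_days"], float),
        circadian_amplitude=np.asarray(d["circadian_amplitude"], float),
        circadian_peak=np.asarray(d["circadian_peak"], float),
        weekend_shift=np.asarray(d["weekend_shift"], float),
        context=context,
        compliance=comp,
    )
    dgp.validate()
    return dgp


def save_dgp(dgp: DgpParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dgp_to_dict(dgp), fh, sort_keys=False)


def load_dgp(path) -> DgpParameters:
    with open(path) as fh:
        return dgp_from_dict(yaml.safe_load(fh))


def write_dataset_csv(dataset: EmaDataset, records_path, schedule_path=None) -> None:
    """Long-format records CSV (subject_id, day_index, clock_time, item_id,
    value); optionally the sent-prompt schedule CSV alongside."""
    rec = dataset.records.copy()
    rec.insert(0, "subject_id", dataset.subject_id)
    rec["clock_time"] = [format_clock(int(m)) for m in rec["clock_time"]]
    rec.to_csv(records_path, index=False)
    if schedule_path is not None:
        sched = dataset.schedule.to_frame(dataset.subject_id)
        sched["answered"] = dataset.answered_mask.astype(int)
        sched.to_csv(schedule_path, index=False)


def read_dataset_csv(records_path, schedule_path, design: StudyDesign) -> EmaDataset:
    """Rebuild an EmaDataset from the two CSVs written by write_dataset_csv."""
    rec = pd.read_csv(records_path)
    sched_df = pd.read_csv(schedule_path)
    schedule = build_prompt_schedule(design)
    if len(sched_df) != len(schedule):
        raise EmadynError(
            f"schedule CSV has {len(sched_df)} prompts but the design implies {len(schedule)}"
        )
    rec["clock_time"] = [parse_clock(c) for c in rec["clock_time"]]
    subject_id = str(rec["subject_id"].iloc[0]) if len(rec) else design.subject_id
    return EmaDataset(
        subject_id=subject_id,
        design=design,
        schedule=schedule,
        records=rec[RECORD_COLUMNS].reset_index(drop=True),
        answered_mask=sched_df["answered"].to_numpy(dtype=bool),
    )
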