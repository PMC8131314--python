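"""Monte-Carlo studies at the study's own scale.

These are the package's calibration and validation experiments: type-I
error of the edge tests under a null generator, recovery of a known
standardized cross-lag through the full pipeline, and the cohort
compliance-decay time course.  They run the same public operations a user
would call, replicate by replicate, with seeds derived from one master
seed.

Conditions mirror the protocol: 42 days x 5 prompts/day (08:00-22:59 every
3 h), 42% of prompts missing completely at random.  Rates are computed
over between-variable edges (cross-lagged and contemporaneous) — the edges
a network report displays; autoregressive self-effects are tracked
separately because the moving-average detrend is known to distort them
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .compliance import compliance_time_course, fit_decay_slope
from .dynamic_network import RelevanceCriteria, estimate_network
from .ema_design import StudyDesign
from .errors import InsufficientDataError
from .synthetic_cohort import (
    CompliancePlan,
    DgpParameters,
    make_dgp,
    simulate_cohort,
    simulate_subject,
    apply_missingness,
)

__all__ = [
    "study_design",
    "crosslag_dgp",
    "type1_calibration",
    "parameter_recovery",
    "compliance_decay_study",
]

#: Share of prompts answered in the calibration/recovery studies
#: (42% of prompts missing, MCAR).
STUDY_ANSWER_PROB = 0.58


def study_design(subject_id: str = "sim", n_days: int = 42) -> StudyDesign:
    """The nominal protocol design: default waking window, 3-hour interval,
    five prompts per day."""
    return StudyDesign(subject_id=subject_id, n_days=n_days)


def crosslag_dgp(
    effect: float,
    answer_prob: float = STUDY_ANSWER_PROB,
    variables: tuple[str, str] = ("fatigue", "worry"),
) -> DgpParameters:
    """Two-variable DGP with a single standardized cross-lag
    ``target <- source`` of the given size (worry at t-1 driving fatigue at
    t when ``effect`` > 0) and nothing else: no autoregression, trend,
    circadian, weekend or contemporaneous structure.

    Innovations are calibrated so stationary variances are 1, making the
    generator effect directly comparable to the estimated standardized
    beta.  Compliance is flat at ``answer_prob``.
    """
    phi = np.array([[0.0, effect], [0.0, 0.0]])
    return make_dgp(
        variables,
        phi,
        compliance=CompliancePlan(p0=answer_prob, daily_decay=1.0),
    )


def _replicate(dgp: DgpParameters, design: StudyDesign, child_seed):
    sim_seed, miss_seed = child_seed.spawn(2)
    full = simulate_subject(design, dgp, sim_seed)
    return apply_missingness(full, dgp, miss_seed)


def type1_calibration(
    n_reps: int = 1000,
    seed: int = 0,
    n_days: int = 42,
    answer_prob: float = STUDY_ANSWER_PROB,
    alpha: float = 0.05,
    criteria: RelevanceCriteria | None = None,
) -> dict:
    """Edge-flagging rate at level ``alpha`` under the null generator.

    Returns the between-variable edge rate (cross-lagged + contemporaneous
    pooled, plus each separately), the self-edge rate, and the relevance-
    filter retention rate of the designated ``fatigue <- worry`` edge
    (its false-retention rate, since the truth is zero).
    """
    criteria = criteria or RelevanceCriteria()
    dgp = crosslag_dgp(0.0, answer_prob=answer_prob)
    design = study_design(n_days=n_days)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    cross_p, contemp_p, self_p = [], [], []
    retained = 0
    fitted = 0
    pairs_used = []
    for child in children:
        ds = _replicate(dgp, design, child)
        try:
            model = estimate_network(ds, dgp.variables)
        except InsufficientDataError:
            continue
        fitted += 1
        pairs_used.append(model.n_lag_pairs)
        focal_edge = None
        for e in model.lagged_edges:
            if e.is_self:
                self_p.append(e.p)
            else:
                cross_p.append(e.p)
            if e.source == "worry" and e.target == "fatigue":
                focal_edge = e
        for e in model.contemporaneous_edges:
            contemp_p.append(e.p)
        if focal_edge is not None and criteria.keeps(focal_edge.beta, focal_edge.p):
            retained += 1
    cross_p = np.asarray(cross_p)
    contemp_p = np.asarray(contemp_p)
    self_p = np.asarray(self_p)
    network_p = np.concatenate([cross_p, contemp_p])
    return {
        "n_reps": n_reps,
        "n_fitted": fitted,
        "mean_lag_pairs": float(np.mean(pairs_used)) if pairs_used else float("nan"),
        "edge_flag_rate": float(np.mean(network_p < alpha)),
        "cross_lagged_flag_rate": float(np.mean(cross_p < alpha)),
        "contemporaneous_flag_rate": float(np.mean(contemp_p < alpha)),
        "self_edge_flag_rate": float(np.mean(self_p < alpha)),
        "null_retention_rate": retained / fitted if fitted else float("nan"),
        "alpha": alpha,
    }


def parameter_recovery(
    effect: float = 0.4,
    n_reps: int = 200,
    seed: int = 0,
    n_days: int = 42,
    answer_prob: float = STUDY_ANSWER_PROB,
    criteria: RelevanceCriteria | None = None,
) -> dict:
    """Recovery of a known standardized cross-lag through the full pipeline.

    Reports the mean estimate, bias, RMSE and the power of the full
    relevance filter (p < alpha and |beta| > beta_min) for the true
    ``fatigue <- worry`` edge.
    """
    criteria = criteria or RelevanceCriteria()
    dgp = crosslag_dgp(effect, answer_prob=answer_prob)
    design = study_design(n_days=n_days)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    estimates = []
    kept = 0
    fitted = 0
    for child in children:
        ds = _replicate(dgp, design, child)
        try:
            model = estimate_network(ds, dgp.variables)
        except InsufficientDataError:
            continue
        fitted += 1
        edge = next(
            e for e in model.lagged_edges if e.source == "worry" and e.target == "fatigue"
        )
        estimates.append(edge.beta)
        if criteria.keeps(edge.beta, edge.p):
            kept += 1
    est = np.asarray(estimates)
    return {
        "true_beta": effect,
        "n_reps": n_reps,
        "n_fitted": fitted,
        "mean_estimate": float(est.mean()),
        "bias": float(est.mean() - effect),
        "rmse": float(np.sqrt(np.mean((est - effect) ** 2))),
        "sd": float(est.std(ddof=1)),
        "filter_power": kept / fitted if fitted else float("nan"),
    }


def compliance_decay_study(
    n_subjects: int = 57,
    seed: int = 0,
    n_days: int = 42,
    p0: float = 0.52,
    daily_decay: float = 0.993,
) -> dict:
    """Cohort compliance time course under geometrically decaying answer
    probability, with the fitted log-linear slope of the daily totals.

    Under the generator the expected daily total is
    ``n_subjects * per_day * p0 * daily_decay**day``, so the fitted slope
    estimates ``log(daily_decay)``.
    """
    dgp = crosslag_dgp(0.0)
    dgp = replace(dgp, compliance=CompliancePlan(p0=p0, daily_decay=daily_decay))
    design = study_design(n_days=n_days)
    cohort = simulate_cohort(n_subjects, design, dgp, master_seed=seed)
    counts = compliance_time_course(cohort)
    slope, slope_se = fit_decay_slope(counts)
    total_sent = sum(len(ds.schedule) for ds in cohort)
    total_answered = sum(ds.n_answered for ds in cohort)
    return {
        "n_subjects": n_subjects,
        "n_days": n_days,
        "daily_counts": counts.tolist(),
        "fitted_log_slope": slope,
        "fitted_log_slope_se": slope_se,
        "true_log_decay": float(np.log(daily_decay)),
        "overall_answer_rate": total_answered / total_sent,
        "expected_answer_rate": dgp.compliance.expected_answer_fraction(n_days),
    }
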