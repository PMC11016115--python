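"""Single-rate state-space model of trial-by-trial visuomotor adaptation.

The model describes how the internal state :math:`x_t` (expressed in the same
units as the observed hand angle, degrees) evolves across trials in response to
the cursor error it experiences::

    e_t     = r_t - x_t
    x_{t+1} = A x_t + B e_t

where ``r_t`` is the imposed cursor rotation on trial ``t`` (counterclockwise
positive), ``A`` is the retention rate (fraction of the state carried to the
next trial) and ``B`` is the adaptation rate (fraction of the experienced error
incorporated into the next state).  Angles follow the compensatory sign
convention: a positive hand angle points opposite the imposed rotation, so
``e_t = r_t - x_t`` shrinks as adaptation proceeds.

``A`` and ``B`` are estimated by ordinary least squares of ``x_{t+1}`` on the
two regressors ``[x_t, e_t]`` with no intercept, treating the observed hand
angle as the state.  An optional intercept is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RotationSchedule",
    "StateSpaceFit",
    "AdaptationSummary",
    "build_rotation_schedule",
    "simulate_state_space",
    "estimate_state_space",
    "adaptation_metrics",
    "UnidentifiableModelError",
]

ADAPTATION_BLOCKS = (2, 3, 4, 5)  # 1-based block indices of the 4 adaptation blocks


class UnidentifiableModelError(ValueError):
    """Raised when the regression design is rank deficient (e.g. a constant
    zero hand-angle series), so A and B cannot be separated."""


@dataclass(frozen=True)
class RotationSchedule:
    """Per-trial cursor rotation in degrees, counterclockwise positive.

    ``r`` covers one task's full trial sequence; baseline and washout entries
    are zero and the adaptation segment is non-decreasing up to the ceiling.
    """

    r: np.ndarray
    n_baseline: int
    n_adapt: int
    n_washout: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if len(self.r) != self.n_baseline + self.n_adapt + self.n_washout:
            raise ValueError("schedule length does not match block sizes")

    @property
    def adaptation(self) -> np.ndarray:
        """Rotation over the adaptation trials only."""
        return self.r[self.n_baseline : self.n_baseline + self.n_adapt]


@dataclass(frozen=True)
class StateSpaceFit:
    """Least-squares estimate of the state-space learner on one series."""

    A_hat: float
    B_hat: float
    r2: float
    predicted_x: np.ndarray
    residuals: np.ndarray
    intercept: float = 0.0
    n_pairs: int = 0


@dataclass(frozen=True)
class AdaptationSummary:
    """Block-level behavioural summary for one subject x task series."""

    block_mean_hand_angle: np.ndarray  # degrees, one per adaptation block
    block_mean_abs_error: np.ndarray  # degrees, |r_t - x_t| per adaptation block
    baseline_sd: float  # degrees
    aftereffect: float  # degrees, mean washout hand angle
    block_mean_rt: dict = field(default_factory=dict)  # seconds, baseline + 4 blocks
    block_mean_mt: dict = field(default_factory=dict)  # seconds, baseline + 4 blocks


def build_rotation_schedule(
    n_baseline: int = 30,
    n_adapt: int = 120,
    n_washout: int = 30,
    increment: float = 0.2,
    ceiling: float = 20.0,
) -> RotationSchedule:
    """Gradual-rotation schedule: zero at baseline, a ramp of ``increment``
    degrees per trial capped at ``ceiling`` during adaptation, zero at washout.

    The ramp is indexed so adaptation trial ``t`` (1-based) has rotation
    ``min(increment * (t - 1), ceiling)``: with the defaults the rotation first
    reaches 20 deg on the 101st adaptation trial and the remaining 19 trials
    stay at the ceiling.
    """
    if min(n_baseline, n_adapt, n_washout) < 0:
        raise ValueError("block lengths must be non-negative")
    if increment < 0 or ceiling < 0:
        raise ValueError("increment and ceiling must be non-negative")
    ramp = np.minimum(increment * np.arange(n_adapt), ceiling)
    r = np.concatenate([np.zeros(n_baseline), ramp, np.zeros(n_washout)])
    return RotationSchedule(r, n_baseline, n_adapt, n_washout)


def simulate_state_space(
    schedule: np.ndarray | RotationSchedule,
    A: float,
    B: float,
    x1: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Iterate the learner over a rotation schedule and return the state series.

    ``x[0] = x1`` and ``x[t+1] = A x[t] + B (r[t] - x[t]) + eta[t]`` with
    ``eta ~ N(0, noise_sd^2)``.  The returned series has the same length as the
    schedule.  With ``noise_sd=0`` the recursion is exact to machine precision.
    """
    r = schedule.r if isinstance(schedule, RotationSchedule) else np.asarray(schedule, float)
    if A < 0:
        raise ValueError("retention rate A must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(r)
    x = np.empty(n)
    if n == 0:
        return x
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    x[0] = x1
    for t in range(n - 1):
        x[t + 1] = A * x[t] + B * (r[t] - x[t]) + noise[t]
    return x


def estimate_state_space(
    hand_angles: np.ndarray,
    schedule: np.ndarray | RotationSchedule,
    valid: np.ndarray | None = None,
    intercept: bool = False,
) -> StateSpaceFit:
    """Estimate retention rate A and adaptation rate B by linear regression.

    ``hand_angles`` are the observed angles over the adaptation trials, aligned
    with the adaptation segment of ``schedule``.  The regression fits
    ``x_{t+1} = A x_t + B e_t`` with ``e_t = r_t - x_t`` formed from the
    observations, no intercept by default.  A trial pair ``(t, t+1)`` enters
    only if both trials are marked valid (``valid`` flags excluded trials).

    R^2 is the ordinary coefficient of determination of the one-step-ahead
    predictions of ``x_{t+1}``.
    """
    x = np.asarray(hand_angles, dtype=float)
    r = schedule.adaptation if isinstance(schedule, RotationSchedule) else np.asarray(schedule, float)
    if len(x) != len(r):
        raise ValueError("hand_angles and adaptation schedule lengths differ")
    ok = np.ones(len(x), bool) if valid is None else np.asarray(valid, bool)
    pair = ok[:-1] & ok[1:]
    if pair.sum() < 3:
        raise ValueError("need at least 3 usable adaptation trial pairs")
    xt = x[:-1][pair]
    et = (r[:-1] - x[:-1])[pair]
    y = x[1:][pair]
    X = np.column_stack([xt, et])
    if intercept:
        X = np.column_stack([X, np.ones(len(xt))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnidentifiableModelError(
            "regression design is rank deficient; A and B are not identifiable"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    c = float(beta[2]) if intercept else 0.0
    return StateSpaceFit(
        A_hat=float(beta[0]),
        B_hat=float(beta[1]),
        r2=r2,
        predicted_x=pred,
        residuals=resid,
        intercept=c,
        n_pairs=int(pair.sum()),
    )


def adaptation_metrics(kin: pd.DataFrame, schedule: RotationSchedule) -> AdaptationSummary:
    """Block-level summary of one subject x task kinematics table.

    Expects columns ``block_index`` (1..6), ``block_role``, ``trial_overall``,
    ``hand_angle_deg``, ``excluded`` and optionally ``reaction_time_s`` /
    ``movement_time_s``.  Excluded trials are dropped from every statistic.
    The per-block mean absolute error is the mean of ``|r_t - x_t|`` -- the
    angle between the (rotated) cursor and the target.
    """
    kin = kin.sort_values("trial_overall")
    use = kin[~kin["excluded"].astype(bool)]
    r_by_trial = dict(zip(range(1, len(schedule.r) + 1), schedule.r))

    angles, abs_err = [], []
    for b in ADAPTATION_BLOCKS:
        blk = use[use["block_index"] == b]
        if blk.empty:
            raise ValueError(f"adaptation block {b} has no usable trials")
        x = blk["hand_angle_deg"].to_numpy(float)
        r = np.array([r_by_trial[t] for t in blk["trial_overall"]])
        angles.append(x.mean())
        abs_err.append(np.abs(r - x).mean())

    base = use[use["block_role"] == "baseline"]
    wash = use[use["block_role"] == "washout"]
    if base.empty or wash.empty:
        raise ValueError("baseline or washout block empty after exclusions")
    baseline_sd = float(base["hand_angle_deg"].std(ddof=1))
    aftereffect = float(wash["hand_angle_deg"].mean())

    rt, mt = {}, {}
    if "reaction_time_s" in use.columns:
        for name, blk in [("baseline", base)] + [
            (f"adaptation_{i}", use[use["block_index"] == b])
            for i, b in enumerate(ADAPTATION_BLOCKS, 1)
        ]:
            rt[name] = float(blk["reaction_time_s"].mean())
            if "movement_time_s" in use.columns:
                mt[name] = float(blk["movement_time_s"].mean())
    return AdaptationSummary(
        block_mean_hand_angle=np.array(angles),
        block_mean_abs_error=np.array(abs_err),
        baseline_sd=baseline_sd,
        aftereffect=aftereffect,
        block_mean_rt=rt,
        block_mean_mt=mt,
    )
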