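"""Behavioural inference: paired t tests with Cohen's d and two-way
repeated-measures ANOVA with partial eta squared.

The ANOVA assumes a complete, balanced fully-within design (every subject
observed in every factor-A x factor-B cell).  Error strata are the classical
subject-by-factor interactions; no sphericity correction is applied, so the
degrees of freedom are the integer textbook values (e.g. task (1, 7) and
block (3, 21) for 8 subjects x 2 tasks x 4 blocks).  Partial eta squared is
``SS_effect / (SS_effect + SS_error)`` with each effect's own error stratum.

Two Cohen's d conventions are provided for the paired test: ``dz`` (mean
difference over the SD of the differences, the default) and ``dav`` (mean
difference over the average of the two condition SDs); the convention used is
recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedTestResult", "paired_t_cohen_d", "rm_anova_two_way"]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float
    d_convention: str
    mean_diff: float


def paired_t_cohen_d(
    x: np.ndarray, y: np.ndarray, d_convention: str = "dz"
) -> PairedTestResult:
    """Two-sided paired t test with Cohen's d.

    ``t = mean(x - y) / (SD(x - y) / sqrt(n))`` on ``df = n - 1``; ``dz`` is
    ``mean(x - y) / SD(x - y)`` (so ``dz = t / sqrt(n)``), ``dav`` divides the
    mean difference by the average of the two condition SDs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    md = d.mean()
    if sd == 0.0:
        if md != 0.0:
            raise ZeroDivisionError(
                "zero difference variance with nonzero mean difference: t is infinite"
            )
        t = 0.0
    else:
        t = md / (sd / np.sqrt(n))
    df = n - 1
    p = 1.0 if (sd == 0.0 and md == 0.0) else 2.0 * sps.t.sf(abs(t), df)
    if d_convention == "dz":
        eff = 0.0 if sd == 0.0 else md / sd
    elif d_convention == "dav":
        s_av = 0.5 * (x.std(ddof=1) + y.std(ddof=1))
        eff = 0.0 if s_av == 0.0 else md / s_av
    else:
        raise ValueError(f"unknown d convention: {d_convention!r}")
    return PairedTestResult(float(t), df, float(p), float(eff), d_convention, float(md))


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a complete balanced long table.

    Returns one row per effect (``factor_a``, ``factor_b``, interaction) with
    ``SS_effect, SS_error, df_effect, df_error, MS_effect, MS_error, F, p,
    partial_eta_sq``.  Raises on incomplete or unbalanced designs.
    """
    cols = [subject, factor_a, factor_b]
    if data.duplicated(cols).any():
        raise ValueError("duplicate subject x cell observations; design must have one value per cell")
    wide = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete design: every subject needs every factor cell")
    subjects = wide.index
    a_levels = sorted(data[factor_a].unique(), key=str)
    b_levels = sorted(data[factor_b].unique(), key=str)
    ns, na, nb = len(subjects), len(a_levels), len(b_levels)
    # y[s, a, b]
    y = np.empty((ns, na, nb))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            y[:, i, j] = wide[(a, b)].to_numpy(float)

    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = ns * nb * np.sum((m_a - m) ** 2)
    ss_b = ns * na * np.sum((m_b - m) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_sa = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_sb = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - m
    )
    ss_sab = np.sum(resid**2)

    effects = [
        (factor_a, ss_a, na - 1, ss_sa, (na - 1) * (ns - 1)),
        (factor_b, ss_b, nb - 1, ss_sb, (nb - 1) * (ns - 1)),
        (f"{factor_a} * {factor_b}", ss_ab, (na - 1) * (nb - 1), ss_sab, (na - 1) * (nb - 1) * (ns - 1)),
    ]
    rows = []
    for name, ss_e, df_e, ss_err, df_err in effects:
        ms_e = ss_e / df_e
        ms_err = ss_err / df_err
        f = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e == 0 else np.inf)
        p = float(sps.f.sf(f, df_e, df_err)) if np.isfinite(f) else 0.0
        pes = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
        rows.append(
            dict(
                effect=name,
                SS_effect=ss_e,
                SS_error=ss_err,
                df_effect=df_e,
                df_error=df_err,
                MS_effect=ms_e,
                MS_error=ms_err,
                F=f,
                p=p,
                partial_eta_sq=pes,
            )
        )
    return pd.DataFrame(rows)
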