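"""Inferential machinery for postanticipation lag-CRP contrasts.

Paired and independent t tests, one-way between-subjects ANOVA, and
default-prior (JZS) Bayes factors, plus a driver that runs the standard
contrast suite: within each list type, fill-in (-1 lag) versus infill
(+1 lag); across list types, the -1, +1 and -5 lag probabilities for each
available pairing.  Lags -5, -1 and +1 are the theoretically loaded ones:
-1 and +1 index the fill-in and infill rates, and -5 is the wrap
transition that the cyclic structure of spun lists elevates.

Participants with no data at an analyzed lag are dropped pairwise for that
test only.  Frequentist tests delegate to scipy.stats; the JZS Bayes
factor is computed here by numerical integration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from .crp import LagCRPTable, participant_crp_frame

__all__ = [
    "StatResult",
    "ContrastSpec",
    "t_test",
    "oneway_anova",
    "jzs_bf10",
    "default_contrast_specs",
    "run_contrast_suite",
]

logger = logging.getLogger(__name__)

DEFAULT_JZS_SCALE = math.sqrt(2) / 2

#: Lags analyzed by the contrast suite.
ANALYZED_LAGS = (-5, -1, 1)


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    test_kind: str               # paired_t | independent_t | oneway_anova
    name: str
    estimate: float              # mean difference (t tests) or F
    statistic: float             # t or F
    p: float
    n_used: int
    se: float | None = None      # SE of the difference (t tests)
    df: float | None = None
    df_between: int | None = None
    df_within: int | None = None
    bf10: float | None = None


def _clean_pair(a, b, mode: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if a.shape != b.shape:
            raise ValueError("paired t test requires aligned samples")
        keep = ~(np.isnan(a) | np.isnan(b))
        return a[keep], b[keep]
    return a[~np.isnan(a)], b[~np.isnan(b)]


def _t_from_parts(estimate: float, se: float, df: int) -> tuple[float, float]:
    """t statistic and two-sided p, with the zero-variance limits
    (t = 0, p = 1 for a zero difference; +/-inf, p = 0 otherwise)."""
    if se == 0.0:
        if estimate == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, estimate), 0.0
    t = estimate / se
    return t, float(2 * sps.t.sf(abs(t), df))


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "paired",
    name: str = "",
    jzs_scale: float = DEFAULT_JZS_SCALE,
) -> StatResult:
    """Two-sided t test with the difference estimate, its SE and BF10.

    Paired mode drops participants with a missing value in either
    condition (pairwise deletion); independent mode uses the pooled
    (equal-variance) Student form.
    """
    if mode not in ("paired", "independent"):
        raise ValueError("mode must be 'paired' or 'independent'")
    a, b = _clean_pair(a, b, mode)
    if mode == "paired":
        n = len(a)
        if n < 2:
            raise InsufficientDataError(f"{name}: {n} usable pairs")
        diff = a - b
        estimate = float(diff.mean())
        se = float(diff.std(ddof=1) / math.sqrt(n))
        statistic, p = _t_from_parts(estimate, se, df := n - 1)
        bf = (
            jzs_bf10(statistic, n, scale=jzs_scale)
            if math.isfinite(statistic) else None
        )
        n_used = n
        kind = "paired_t"
    else:
        n1, n2 = len(a), len(b)
        if n1 < 2 or n2 < 2:
            raise InsufficientDataError(f"{name}: groups of {n1} and {n2}")
        estimate = float(a.mean() - b.mean())
        sp2 = (
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
            / (n1 + n2 - 2)
        )
        se = float(math.sqrt(sp2 * (1 / n1 + 1 / n2)))
        statistic, p = _t_from_parts(estimate, se, df := n1 + n2 - 2)
        bf = (
            jzs_bf10(statistic, n1, n2, scale=jzs_scale)
            if math.isfinite(statistic) else None
        )
        n_used = n1 + n2
        kind = "independent_t"
    return StatResult(
        test_kind=kind, name=name, estimate=estimate, se=se,
        statistic=statistic, df=df, p=p, bf10=bf, n_used=n_used,
    )


def oneway_anova(
    groups: Mapping[str, Sequence[float]], name: str = ""
) -> StatResult:
    """One-way between-subjects ANOVA (e.g. experiment as the factor)."""
    cleaned = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) == 0:
            logger.warning("ANOVA %s: dropping empty group %r", name, label)
            continue
        cleaned[label] = v
    k = len(cleaned)
    n_total = sum(len(v) for v in cleaned.values())
    if k < 2 or n_total - k < 1:
        raise InsufficientDataError(f"{name}: {k} groups, {n_total} values")
    f, p = sps.f_oneway(*cleaned.values())
    return StatResult(
        test_kind="oneway_anova", name=name, estimate=float(f),
        statistic=float(f), p=float(p), n_used=n_total,
        df_between=k - 1, df_within=n_total - k,
    )


def jzs_bf10(
    t: float,
    n1: int,
    n2: int | None = None,
    scale: float = DEFAULT_JZS_SCALE,
) -> float:
    """Two-sided default-prior (JZS) Bayes factor BF10 for a t statistic.

    The alternative places a Cauchy prior with width ``scale`` on the
    standardized effect size, equivalently a scaled inverse-chi-square
    prior on the relative prior variance g, which is integrated out
    numerically (Zellner-Siow / Jeffreys mixture).  One-sample or paired
    when ``n2`` is absent (effective sample size n1, df n1-1); two-sample
    otherwise (effective sample size n1*n2/(n1+n2), df n1+n2-2).

    The default width sqrt(2)/2 is the "medium" default of the common
    Bayes-factor software family.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        n_eff = float(n1)
        df = n1 - 1
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("need both group sizes >= 2")
        n_eff = n1 * n2 / (n1 + n2)
        df = n1 + n2 - 2
    t2 = t * t
    r2 = scale * scale
    # Integrand expressed relative to the null marginal, so the quotient of
    # two astronomically small marginals never materialises.
    log_null = -(df + 1) / 2 * math.log1p(t2 / df)

    def integrand(g: float) -> float:
        c = 1.0 + n_eff * g * r2
        log_alt = -0.5 * math.log(c) - (df + 1) / 2 * math.log1p(t2 / (c * df))
        log_prior = -0.5 * math.log(2 * math.pi) - 1.5 * math.log(g) - 1 / (2 * g)
        return math.exp(log_alt + log_prior - log_null)

    value, abserr = integrate.quad(integrand, 0.0, np.inf, limit=400)
    if not math.isfinite(value) or (value > 0 and abserr / value > 1e-4):
        raise RuntimeError(
            f"JZS integration did not converge: value={value}, abserr={abserr}"
        )
    return value


@dataclass(frozen=True)
class ContrastSpec:
    """One postanticipation lag-CRP contrast (paired over participants)."""

    name: str
    list_type_a: str
    lag_a: int
    list_type_b: str
    lag_b: int

    def __post_init__(self) -> None:
        for lag in (self.lag_a, self.lag_b):
            if lag not in ANALYZED_LAGS:
                raise ValueError(f"lag {lag} is not analyzed {ANALYZED_LAGS}")


#: Pairings in canonical order: item-independent-friendly designs first.
_PAIR_ORDER = (("same", "spun"), ("spun", "scrambled"), ("same", "scrambled"))


def default_contrast_specs(list_types: Sequence[str]) -> list[ContrastSpec]:
    """Standard contrast suite for the available list types.

    Per list type, fill-in tendency (-1 vs +1).  Per available pairing,
    +1, -1 and -5 across list types.  Two list types yield 5 contrasts;
    three yield 12.
    """
    present = [lt for lt in ("same", "spun", "scrambled") if lt in list_types]
    specs = [
        ContrastSpec(f"{lt} -1 vs {lt} +1", lt, -1, lt, +1) for lt in present
    ]
    for x, y in _PAIR_ORDER:
        if x in present and y in present:
            for lag in (+1, -1, -5):
                sign = f"{lag:+d}"
                specs.append(
                    ContrastSpec(f"{x} {sign} vs {y} {sign}", x, lag, y, lag)
                )
    return specs


def run_contrast_suite(
    tables: Sequence[LagCRPTable],
    specs: Sequence[ContrastSpec] | None = None,
    jzs_scale: float = DEFAULT_JZS_SCALE,
) -> pd.DataFrame:
    """Run paired contrasts on participant-level postanticipation CRPs.

    Returns one row per contrast with the Tables-5/6-style columns
    (test, M_diff, SE_diff, t, df, p, BF10, n).  Specs referencing a list
    type absent from the data are skipped with a warning.
    """
    frame = participant_crp_frame(list(tables))
    if not frame.empty and (frame["mode"] != "postanticipation").any():
        raise ValueError("contrast suite runs on postanticipation tables")
    available = set(frame["list_type"].unique()) if not frame.empty else set()
    if specs is None:
        specs = default_contrast_specs(sorted(available))
    wide = (
        frame.pivot_table(
            index="participant", columns=["list_type", "lag"], values="crp"
        )
        if not frame.empty
        else pd.DataFrame()
    )
    rows = []
    for spec in specs:
        if spec.list_type_a not in available or spec.list_type_b not in available:
            logger.warning(
                "skipping contrast %r: list type not in data", spec.name
            )
            continue
        try:
            a = wide[(spec.list_type_a, spec.lag_a)]
            b = wide[(spec.list_type_b, spec.lag_b)]
        except KeyError:
            logger.warning("skipping contrast %r: no data at lag", spec.name)
            continue
        try:
            res = t_test(a, b, mode="paired", name=spec.name, jzs_scale=jzs_scale)
        except InsufficientDataError as err:
            logger.warning("skipping contrast %r: %s", spec.name, err)
            continue
        rows.append(
            {
                "test": spec.name,
                "M_diff": res.estimate,
                "SE_diff": res.se,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "BF10": res.bf10,
                "n": res.n_used,
            }
        )
    return pd.DataFrame(
        rows, columns=["test", "M_diff", "SE_diff", "t", "df", "p", "BF10", "n"]
    )
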