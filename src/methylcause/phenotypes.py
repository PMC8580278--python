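"""Smoking exposure codings and beta/M-value conversion.

The exposure of interest is a seven-level ordinal smoking phenotype combining
smoking status (never / former / current) with lifetime dose in pack-years
(packs per day x years smoked):

    0  never
    1  former,  <= 10.0 pack-years
    2  former,  10.1 - 20.0 pack-years
    3  former,  >= 20.1 pack-years
    4  current, <= 10.0 pack-years
    5  current, 10.1 - 20.0 pack-years
    6  current, >= 20.1 pack-years

A three-level change variable compares status across two measurement waves:
0 = decrease (current -> former), 1 = no change (never -> never,
former -> former), 2 = increase (never -> former, never -> current,
former -> current, current -> current).  Continuing current smokers count as
an increase because smoke exposure keeps accumulating between waves.

Methylation beta-values (proportion methylated, open interval (0,1)) and
M-values (base-2 logit of beta) are interconvertible; analyses that plant or
estimate linear effects do so on the M scale where effects are unbounded.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NEVER = "never"
FORMER = "former"
CURRENT = "current"
STATUSES = (NEVER, FORMER, CURRENT)

DECREASE = 0
NO_CHANGE = 1
INCREASE = 2
CHANGE_LABELS = {DECREASE: "decrease", NO_CHANGE: "no_change", INCREASE: "increase"}

# Pack-year band edges.  The printed bands are "<=10.0", "10.1-20.0", ">=20.1";
# real-valued pack-years in (10.0, 10.1) or (20.0, 20.1) fall between printed
# edges, so the operational rule is half-open: (10, 20] is the middle band,
# > 20 the top band.
PACK_YEAR_CUTS = (10.0, 20.0)

_CHANGE_MAP = {
    (CURRENT, FORMER): DECREASE,
    (NEVER, NEVER): NO_CHANGE,
    (FORMER, FORMER): NO_CHANGE,
    (NEVER, FORMER): INCREASE,
    (NEVER, CURRENT): INCREASE,
    (FORMER, CURRENT): INCREASE,
    (CURRENT, CURRENT): INCREASE,
}


def _check_status(status: str) -> str:
    if status not in STATUSES:
        raise ValueError(f"unknown smoking status {status!r}; expected one of {STATUSES}")
    return status


def derive_smoking_phenotype(status: str, pack_years: float | None) -> float:
    """Map (status, pack-years) to the 0-6 ordinal smoking phenotype.

    Returns NaN when pack-years are missing for an ever-smoker; such records
    are excluded from downstream analyses rather than imputed.
    """
    _check_status(status)
    if status == NEVER:
        return 0.0
    if pack_years is None or (isinstance(pack_years, float) and np.isnan(pack_years)):
        return float("nan")
    if pack_years < 0:
        raise ValueError(f"pack_years must be nonnegative, got {pack_years}")
    lo, hi = PACK_YEAR_CUTS
    band = 1 if pack_years <= lo else (2 if pack_years <= hi else 3)
    return float(band if status == FORMER else band + 3)


def derive_smoking_phenotype_vector(
    status: Iterable[str], pack_years: Iterable[float]
) -> np.ndarray:
    """Vectorized phenotype derivation; NaN where the coding is undefined."""
    status = np.asarray(list(status), dtype=object)
    py = np.asarray(list(pack_years), dtype=float)
    out = np.empty(len(status), dtype=float)
    for i, (s, p) in enumerate(zip(status, py)):
        out[i] = derive_smoking_phenotype(s, p)
    return out


def classify_smoking_change(status_w1: str, status_w2: str) -> int:
    """Classify a wave-1 -> wave-2 status transition as 0/1/2.

    Raises for former->never and current->never, which are impossible
    transitions and flag a data error.
    """
    key = (_check_status(status_w1), _check_status(status_w2))
    if key not in _CHANGE_MAP:
        raise ValueError(
            f"impossible smoking-status transition {status_w1!r} -> {status_w2!r}"
        )
    return _CHANGE_MAP[key]


def tabulate_changes(roster: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Count decrease / no_change / increase over a roster of status pairs."""
    counts = Counter(classify_smoking_change(a, b) for a, b in roster)
    return {
        "decrease": counts.get(DECREASE, 0),
        "no_change": counts.get(NO_CHANGE, 0),
        "increase": counts.get(INCREASE, 0),
    }


def beta_to_m(beta, clamp: bool = False, eps: float = 1e-6):
    """Base-2 logit: M = log2(beta / (1 - beta)).

    beta must lie strictly in (0,1); with ``clamp=True`` values outside
    [eps, 1-eps] are clamped instead of rejected.
    """
    beta = np.asarray(beta, dtype=float)
    if clamp:
        beta = np.clip(beta, eps, 1.0 - eps)
    elif np.any((beta <= 0.0) | (beta >= 1.0)):
        raise ValueError("beta-values must lie strictly in (0, 1); set clamp=True to clamp")
    out = np.log2(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1), strictly in (0,1)."""
    m = np.asarray(m, dtype=float)
    # expit(x*log 2) computed stably
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


def augment_phenotype_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add derived phenotype and change columns to a two-wave phenotype table.

    Expects columns status_w1, status_w2, packyears_w1, packyears_w2.
    """
    out = pheno.copy()
    out["phenotype_w1"] = derive_smoking_phenotype_vector(
        pheno["status_w1"], pheno["packyears_w1"]
    )
    out["phenotype_w2"] = derive_smoking_phenotype_vector(
        pheno["status_w2"], pheno["packyears_w2"]
    )
    out["smoking_change"] = [
        classify_smoking_change(a, b)
        for a, b in zip(pheno["status_w1"], pheno["status_w2"])
    ]
    return out
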