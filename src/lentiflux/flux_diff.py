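"""Per-reaction Van der Waerden differential flux testing.

The Van der Waerden (VdW) test replaces pooled ranks R_i (mid-ranks under
ties) with standard-normal quantile scores A_i = Phi^-1(R_i / (N + 1)) and
compares the group-A score sum T between conditions.  Exact mode enumerates
all C(N, n_a) group assignments (cheap at the 7-vs-7 scale, where
C(14, 7) = 3432); normal mode standardizes T by its permutation variance
Var(T) = n_a * n_b * sum(A_j^2) / (N * (N - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .model_io import MetabolicModel

__all__ = [
    "vdw_scores",
    "vdw_test",
    "differential_flux_table",
]

_TIE_TOL = 1e-12


def vdw_scores(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normal scores A_i = Phi^-1(R_i / (N+1)) from mid-ranks R_i."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("normal scores require at least two values")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (v.size + 1))


@lru_cache(maxsize=64)
def _assignment_matrix(n_total: int, n_a: int) -> np.ndarray:
    """All C(N, n_a) index subsets, one row per group-A assignment."""
    return np.array(list(combinations(range(n_total), n_a)), dtype=np.intp)


def vdw_test(
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
    mode: str = "auto",
    max_exact: int = 200_000,
) -> tuple[float, float]:
    """Two-sided VdW test; returns (T, p).

    ``mode``: "exact" (full enumeration of group assignments), "normal"
    (permutation-variance normal approximation) or "auto" (exact whenever
    C(N, n_a) <= ``max_exact``).  Identical pooled values give (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("vdw_test requires >= 2 observations per group")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    n_a, n_b = a.size, b.size
    n_total = n_a + n_b
    scores = vdw_scores(pooled)
    t_obs = float(scores[:n_a].sum())

    if mode == "auto":
        mode = "exact" if comb(n_total, n_a) <= max_exact else "normal"
    if mode == "exact":
        if comb(n_total, n_a) > max_exact:
            raise ValueError(
                f"exact mode needs C({n_total},{n_a}) <= {max_exact} assignments"
            )
        assign = _assignment_matrix(n_total, n_a)
        t_all = scores[assign].sum(axis=1)
        p = float(np.mean(np.abs(t_all) >= abs(t_obs) - _TIE_TOL))
        return t_obs, p

    var_t = n_a * n_b * float(np.sum(scores**2)) / (n_total * (n_total - 1))
    if var_t <= 0:
        return t_obs, 1.0
    z = t_obs / np.sqrt(var_t)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return t_obs, p


def differential_flux_table(
    flux_table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    *,
    lesion: str = "lesion",
    control: str = "control",
    alpha: float = 0.05,
    mode: str = "auto",
    model: MetabolicModel | None = None,
    include_exchanges: bool = False,
) -> pd.DataFrame:
    """VdW test per reaction with BH-FDR across the tested reactions.

    ``flux_table`` is reactions x samples.  Reactions with degenerate
    (constant) pooled flux are reported untested with p = 1 and direction
    "none"; when a ``model`` is supplied, single-metabolite boundary stubs
    (exchanges/demands) are likewise excluded from testing by default, since
    their fluxes only mirror the internal reactions they feed.  The FDR is
    computed over tested reactions only and the significance flag is
    fdr < ``alpha`` (strict).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    samples_l = [s for s in flux_table.columns if groups.get(s) == lesion]
    samples_c = [s for s in flux_table.columns if groups.get(s) == control]
    if len(samples_l) < 2 or len(samples_c) < 2:
        raise ValueError(
            f"need >= 2 samples per group; found {len(samples_l)} {lesion!r} "
            f"and {len(samples_c)} {control!r}"
        )

    exchange_ids: set[str] = set()
    subsystems: dict[str, str] = {}
    if model is not None:
        subsystems = {r.id: r.subsystem for r in model.reactions}
        if not include_exchanges:
            exchange_ids = {r.id for r in model.reactions if r.is_exchange}

    records = []
    for rid, row in flux_table.iterrows():
        vl = row[samples_l].to_numpy(dtype=float)
        vc = row[samples_c].to_numpy(dtype=float)
        pooled = np.concatenate([vl, vc])
        degenerate = (
            np.isnan(pooled).any() or np.ptp(pooled) <= _TIE_TOL
        )
        excluded = rid in exchange_ids
        tested = not degenerate and not excluded
        if tested:
            t_stat, p = vdw_test(vl, vc, mode=mode)
            if t_stat > _TIE_TOL:
                direction = "up"
            elif t_stat < -_TIE_TOL:
                direction = "down"
            else:
                direction = "none"
        else:
            t_stat, p, direction = 0.0, 1.0, "none"
        records.append(
            {
                "reaction": rid,
                "subsystem": subsystems.get(rid, ""),
                "mean_lesion": float(np.nanmean(vl)) if vl.size else np.nan,
                "mean_control": float(np.nanmean(vc)) if vc.size else np.nan,
                "T": t_stat,
                "p": p,
                "direction": direction,
                "tested": tested,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("reaction")
    table["fdr"] = np.nan
    tested_mask = table["tested"].to_numpy()
    if tested_mask.any():
        table.loc[tested_mask, "fdr"] = bh_fdr(
            table.loc[tested_mask, "p"].to_numpy()
        )
    table["significant"] = table["tested"] & (table["fdr"] < alpha)
    return table
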