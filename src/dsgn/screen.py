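"""Drug–gene Pearson correlation screen with the top-decile rounding filter.

The screen computes, for every (drug, gene) pair, the Pearson correlation
between the drug's activity and the gene's expression across a shared
cell-line panel, keeps pairs passing the significance gate
(|PCC| >= r_min and p < p_max), then applies a per-drug filter: the drug's
gated gene count k is rounded up to the next multiple of ten (rd) and only
the top decile * rd pairs by |PCC| are retained — e.g. a drug with 32 gated
genes has rd = 40 and keeps its top 4 pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationRecord:
    """One drug–gene association: the atom of the screen."""

    drug_id: str
    gene_id: str
    pcc: float
    p_value: float
    n_obs: int

    def __post_init__(self) -> None:
        if abs(self.pcc) > 1 + 1e-12:
            raise ValueError(f"|pcc| must be <= 1, got {self.pcc}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.n_obs < 4:
            raise ValueError(f"n_obs must be >= 4, got {self.n_obs}")


@dataclass(frozen=True)
class ScreenConfig:
    """Screen thresholds: correlation gate, significance gate, retained decile."""

    r_min: float = 0.5
    p_max: float = 0.01
    decile: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min < 1.0):
            raise ValueError(f"r_min must be in (0, 1), got {self.r_min}")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")
        if not (0.0 < self.decile <= 1.0):
            raise ValueError(f"decile must be in (0, 1], got {self.decile}")


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant vector."""


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 4).

    Raises :class:`ConstantVectorError` for a constant input rather than
    silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ConstantVectorError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ConstantVectorError("y is constant; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def corr_pvalue(pcc: float, n_obs: int) -> float:
    """Two-sided p-value for a Pearson correlation.

    Uses the exact null distribution of t = r * sqrt(n-2) / sqrt(1-r^2)
    against Student-t with n-2 degrees of freedom. |pcc| = 1 returns 0 by
    convention.
    """
    if n_obs < 4:
        raise ValueError(f"n_obs must be >= 4, got {n_obs}")
    if abs(pcc) > 1:
        raise ValueError(f"|pcc| must be <= 1, got {pcc}")
    if abs(pcc) == 1.0:
        return 0.0
    t = pcc * math.sqrt(n_obs - 2) / math.sqrt(1.0 - pcc * pcc)
    return float(2.0 * stats.t.sf(abs(t), df=n_obs - 2))


def _pairwise_correlations(expr: pd.DataFrame, act: pd.DataFrame) -> np.ndarray:
    """Dense (drugs x genes) PCC matrix over a complete (no-NaN) panel."""
    e = expr.to_numpy(dtype=float)
    a = act.to_numpy(dtype=float)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    return np.clip(az @ ez.T / e.shape[1], -1.0, 1.0)


def screen_pairs(
    expr: pd.DataFrame,
    act: pd.DataFrame,
    cfg: ScreenConfig = ScreenConfig(),
) -> list[CorrelationRecord]:
    """All (drug, gene) pairs passing |PCC| >= r_min and p < p_max.

    Both matrices must carry an identical ordered cell-line header. Missing
    values are handled pair by pair on the complete-case intersection of
    cell lines, with ``n_obs`` recording the count actually used; constant
    vectors within a pair's complete cases are skipped (their correlation is
    undefined).
    """
    if list(expr.columns) != list(act.columns):
        raise ValueError(
            "cell-line sets disagree: expression has "
            f"{list(expr.columns)}, activity has {list(act.columns)}"
        )
    n = expr.shape[1]
    records: list[CorrelationRecord] = []
    has_nan = bool(np.isnan(expr.to_numpy(dtype=float)).any() or np.isnan(act.to_numpy(dtype=float)).any())
    if not has_nan:
        pcc = _pairwise_correlations(expr, act)
        gate = np.abs(pcc) >= cfg.r_min
        for i, j in zip(*np.nonzero(gate)):
            r = float(pcc[i, j])
            p = corr_pvalue(r, n)
            if p < cfg.p_max:
                records.append(CorrelationRecord(str(act.index[i]), str(expr.index[j]), r, p, n))
    else:
        e = expr.to_numpy(dtype=float)
        a = act.to_numpy(dtype=float)
        for i in range(a.shape[0]):
            for j in range(e.shape[0]):
                mask = ~(np.isnan(a[i]) | np.isnan(e[j]))
                n_obs = int(mask.sum())
                if n_obs < 4:
                    continue
                xa, xe = a[i][mask], e[j][mask]
                if np.ptp(xa) == 0 or np.ptp(xe) == 0:
                    continue
                r = float(np.corrcoef(xa, xe)[0, 1])
                if abs(r) >= cfg.r_min:
                    p = corr_pvalue(max(-1.0, min(1.0, r)), n_obs)
                    if p < cfg.p_max:
                        records.append(
                            CorrelationRecord(str(act.index[i]), str(expr.index[j]), r, p, n_obs)
                        )
    records.sort(key=lambda r: (r.drug_id, -abs(r.pcc), r.p_value, r.gene_id))
    return records


def round_up_ten(k: int) -> int:
    """Smallest multiple of 10 that is >= k (e.g. 32 -> 40)."""
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    return 10 * math.ceil(k / 10)


def top_decile_filter(
    records: list[CorrelationRecord],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[CorrelationRecord]:
    """Per-drug retention of the top decile * rd pairs by |PCC|.

    For a drug with k gated records, rd = round_up_ten(k) and exactly
    min(k, decile * rd) records are retained, so every drug that entered
    keeps at least one record. Ties broken by (|pcc| desc, p asc, gene_id)
    for determinism. Idempotent.
    """
    by_drug: dict[str, list[CorrelationRecord]] = {}
    for rec in records:
        by_drug.setdefault(rec.drug_id, []).append(rec)
    out: list[CorrelationRecord] = []
    for drug in sorted(by_drug):
        recs = sorted(by_drug[drug], key=lambda r: (-abs(r.pcc), r.p_value, r.gene_id))
        k = len(recs)
        keep = min(k, max(1, int(round(cfg.decile * round_up_ten(k)))))
        out.extend(recs[:keep])
    return out
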