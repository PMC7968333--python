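"""Genotype-by-environment diagnostics: re-ranking and robustness.

Quantifies how much animal rankings change across the environmental
gradient — the practical consequence of G x E.  Sires are ranked by
gEBV(x) = a0 + x a1 at the realized gradient quantiles and the overlap
of top lists is counted; heifers selected under the two gradient
definitions are compared at equivalent environmental levels; and sires
with preferential intercepts are split into climate-resilient (flat
slope) and climate-sensitive (steep slope) groups.

The favorable direction is trait configuration: lower is better for age
at first calving and the service interval, higher for conception rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import Pedigree

DEFAULT_QUANTILE_PAIRS = ((0.01, 0.99), (0.05, 0.95), (0.10, 0.90), (0.25, 0.75))

FAVORABLE_DIRECTION = {"AFC": "low", "IFL": "low", "CR": "high"}


def daughter_counts(ped: Pedigree, phenotyped_idx: np.ndarray) -> np.ndarray:
    """Number of phenotyped daughters per animal (indexed by pedigree position)."""
    counts = np.zeros(ped.n, dtype=int)
    sires = ped.sire_idx[np.asarray(phenotyped_idx)]
    np.add.at(counts, sires[sires >= 0], 1)
    return counts


def _top_set(gebv: np.ndarray, candidates: np.ndarray, top_n: int, favorable: str):
    order = np.argsort(gebv[candidates], kind="stable")
    if favorable == "high":
        order = order[::-1]
    return set(candidates[order[:top_n]].tolist())


@dataclass
class RankingReport:
    """Top-sire overlap between gradient quantile levels."""

    table: pd.DataFrame
    n_eligible: int
    top_n: int


def sire_overlap(
    results,
    eg_values: np.ndarray,
    ped: Pedigree,
    phenotyped_idx: np.ndarray,
    quantile_pairs=DEFAULT_QUANTILE_PAIRS,
    top_n: int = 50,
    min_daughters: int = 20,
    favorable: str = "low",
) -> RankingReport:
    """Count common sires among the top ``top_n`` at paired EG quantiles.

    Eligible sires have at least ``min_daughters`` phenotyped daughters;
    quantiles are taken from the realized per-record gradient
    distribution.  With fewer than ``top_n`` eligible sires the list
    size shrinks with a warning.
    """
    counts = daughter_counts(ped, phenotyped_idx)
    eligible = np.where(counts >= min_daughters)[0]
    if len(eligible) == 0:
        raise ValueError("no sires pass the daughter-count filter")
    n_top = top_n
    if len(eligible) < top_n:
        warnings.warn(
            f"only {len(eligible)} eligible sires; top list reduced from {top_n}"
        )
        n_top = len(eligible)
    eg_values = np.asarray(eg_values, dtype=float)
    rows = []
    for q_lo, q_hi in quantile_pairs:
        x_lo, x_hi = np.quantile(eg_values, [q_lo, q_hi])
        top_lo = _top_set(results.gebv_at(x_lo), eligible, n_top, favorable)
        top_hi = _top_set(results.gebv_at(x_hi), eligible, n_top, favorable)
        rows.append(
            {
                "q_lo": q_lo, "q_hi": q_hi, "x_lo": x_lo, "x_hi": x_hi,
                "n_common": len(top_lo & top_hi),
            }
        )
    return RankingReport(table=pd.DataFrame(rows), n_eligible=len(eligible), top_n=n_top)


@dataclass
class SireClassification:
    resilient: np.ndarray
    sensitive: np.ndarray
    screened: np.ndarray
    degenerate: bool


def classify_sires(
    results,
    sire_idx: np.ndarray,
    k_top: int = 5,
    favorable: str = "low",
) -> SireClassification:
    """Split preferential-intercept sires into resilient and sensitive.

    The screen keeps sires whose intercept a0 is beyond the mean by two
    standard deviations in the favorable direction; among those, the
    ``k_top`` flattest slopes (smallest absolute a1) are the
    climate-resilient group and the ``k_top`` steepest the sensitive
    group.  With all slopes identical the split is degenerate and
    flagged.
    """
    sire_idx = np.asarray(sire_idx)
    a0 = results.a0[sire_idx]
    a1 = results.a1[sire_idx]
    mu, sd = a0.mean(), a0.std(ddof=1)
    screen = a0 < mu - 2 * sd if favorable == "low" else a0 > mu + 2 * sd
    screened = sire_idx[screen]
    if len(screened) == 0:
        raise ValueError("intercept screen selected no sires")
    slopes = np.abs(a1[screen])
    order = np.argsort(slopes, kind="stable")
    resilient = screened[order[:k_top]]
    sensitive = screened[order[::-1][:k_top]]
    degenerate = bool(np.allclose(slopes.min(), slopes.max()))
    return SireClassification(resilient, sensitive, screened, degenerate)


def equivalent_mthi_levels(
    prop_values: np.ndarray,
    mthi_values: np.ndarray,
    levels=(0.2, 0.4, 0.6, 0.8, 1.0),
    tol: float = 0.1,
) -> pd.DataFrame:
    """Equivalence table between the two gradient definitions.

    For each proportion level, the mean minimum-THI gradient among
    records whose proportion falls within ``tol`` of the level — the
    empirical counterpart of "the average minimum THI of periods whose
    heat-day proportion reaches this level".  Computed from the data,
    not hard-coded.
    """
    prop = np.asarray(prop_values, dtype=float)
    mthi = np.asarray(mthi_values, dtype=float)
    rows = []
    for lev in levels:
        mask = np.abs(prop - lev) <= tol
        rows.append(
            {"prop_level": lev,
             "mthi_level": float(mthi[mask].mean()) if mask.any() else np.nan,
             "n": int(mask.sum())}
        )
    return pd.DataFrame(rows)


def top_heifer_overlap(
    results_prop,
    results_mthi,
    equivalence_pairs,
    heifer_idx: np.ndarray,
    acc_threshold: float = 0.4,
    top_frac: float = 0.01,
    favorable: str = "low",
) -> pd.DataFrame:
    """Overlap of top heifers selected under the two gradients.

    For each (prop level, equivalent mTHI level) pair: keep heifers whose
    EBV accuracy exceeds ``acc_threshold`` under both fits at those
    levels, take the top ``top_frac`` by gEBV under each gradient, and
    report the intersection fraction.
    """
    heifer_idx = np.asarray(heifer_idx)
    rows = []
    for prop_level, mthi_level in equivalence_pairs:
        acc_p = results_prop.accuracy_at(prop_level, heifer_idx)
        acc_m = results_mthi.accuracy_at(mthi_level, heifer_idx)
        pool = heifer_idx[(acc_p > acc_threshold) & (acc_m > acc_threshold)]
        n_top = max(1, int(round(top_frac * len(pool)))) if len(pool) else 0
        if n_top == 0:
            rows.append({"prop_level": prop_level, "mthi_level": mthi_level,
                         "n_pool": 0, "n_top": 0, "overlap": np.nan})
            continue
        top_p = _top_set(results_prop.gebv_at(prop_level), pool, n_top, favorable)
        top_m = _top_set(results_mthi.gebv_at(mthi_level), pool, n_top, favorable)
        rows.append(
            {"prop_level": prop_level, "mthi_level": mthi_level,
             "n_pool": len(pool), "n_top": n_top,
             "overlap": len(top_p & top_m) / n_top}
        )
    return pd.DataFrame(rows)
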