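"""Weighted (GRS) and unweighted (RAC) polygenic scores and strata.

The genetic risk score of individual *i* is the inner product of their
risk-allele dosages with the panel's log-odds-ratio weights,
``GRS_i = sum_j ln(OR_j) * g_ij``; the risk allele count is the
unweighted sum ``RAC_i = sum_j g_ij``.  Stratum assignment (rank-based
quartiles, fixed-size score bins) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .panel import RiskPanel


@dataclass
class ScoreSet:
    """Per-individual RAC, GRS and optional quartile labels."""

    individual_ids: list[str]
    rac: np.ndarray
    grs: np.ndarray
    quartile: np.ndarray | None = field(default=None)  # 1..4 or None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"individual_id": self.individual_ids,
                           "rac": self.rac, "grs": self.grs})
        df["quartile"] = self.quartile if self.quartile is not None else pd.NA
        return df

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)


def compute_scores(
    genotypes: GenotypeMatrix,
    panel: RiskPanel,
    subset: list[str] | None = None,
) -> ScoreSet:
    """Score a complete genotype matrix against a (sub)panel.

    ``subset`` restricts scoring to the named panel SNPs (e.g. an
    HLA-only score); an id absent from the panel raises.  Quartiles are
    unassigned until :func:`assign_quartiles`.
    """
    sub = panel if subset is None else panel.subset(subset)
    if np.isnan(genotypes.dosage).any():
        raise ValueError("missing dosages present; apply filter_complete first")
    idx = genotypes.column_index(sub.snp_ids)
    dos = genotypes.dosage[:, idx]
    rac = dos.sum(axis=1).astype(int)
    grs = dos @ sub.weights
    return ScoreSet(genotypes.individual_ids, rac, grs)


def assign_quartiles(
    scores: ScoreSet,
    reference: str = "all",
    status: np.ndarray | None = None,
) -> ScoreSet:
    """Rank-based quartiles of the GRS (1 = lowest, 4 = highest).

    Individuals are ranked by GRS with a stable sort (ties keep input
    order) and cut into four groups as equal as possible, the remainder
    going to the lowest quartiles first.  With ``reference="cases_only"``
    quartiles are computed among cases (``status`` True) and controls are
    left unassigned.
    """
    grs = np.asarray(scores.grs, float)
    if not np.isfinite(grs).all():
        raise ValueError("scores must be finite")
    if reference not in ("all", "cases_only"):
        raise ValueError(f"unknown reference {reference!r}")
    if reference == "cases_only":
        if status is None:
            raise ValueError("cases_only reference requires status labels")
        mask = np.asarray(status, bool)
    else:
        mask = np.ones(len(grs), bool)
    vals = grs[mask]
    n = len(vals)
    if n < 4:
        raise ValueError("need at least 4 individuals for quartiles")
    if np.ptp(vals) == 0:
        raise ValueError("all scores identical; quartiles undefined")
    order = np.argsort(vals, kind="stable")
    sizes = np.full(4, n // 4)
    sizes[: n % 4] += 1  # remainder to the lowest quartiles
    labels_sorted = np.repeat([1, 2, 3, 4], sizes)
    labels = np.empty(n, int)
    labels[order] = labels_sorted
    quartile = np.full(len(grs), np.nan)
    quartile[mask] = labels
    return ScoreSet(scores.individual_ids, scores.rac, scores.grs, quartile)


def binned_prevalence(
    scores: ScoreSet,
    status: np.ndarray,
    group_size: int = 100,
) -> pd.DataFrame:
    """Disease prevalence in fixed-size groups of increasing GRS.

    Individuals are ordered by GRS ascending and split into groups of
    ``group_size``; the remainder ``n mod group_size`` is merged into the
    first (lowest-score) group.  Returns one row per group with its mean
    GRS and fraction of cases.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    grs = np.asarray(scores.grs, float)
    status = np.asarray(status, bool)
    n = len(grs)
    if n < group_size:
        raise ValueError("fewer individuals than group_size")
    order = np.argsort(grs, kind="stable")
    n_groups = n // group_size
    first = group_size + n % group_size
    bounds = np.cumsum([0, first] + [group_size] * (n_groups - 1))
    rows = []
    for g in range(n_groups):
        idx = order[bounds[g]:bounds[g + 1]]
        rows.append({"group": g + 1, "n": len(idx),
                     "mean_grs": grs[idx].mean(),
                     "prevalence": status[idx].mean()})
    return pd.DataFrame(rows)
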