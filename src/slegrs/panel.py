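"""Risk-SNP weight panels and case/control allelic odds ratios.

A :class:`RiskPanel` carries, per biallelic SNP, the risk-allele
orientation and the log-odds-ratio weight ``w_j = ln(OR_j)`` used by the
weighted genetic risk score.  Weights are estimated from case/control
genotype counts with :func:`estimate_allelic_or` or loaded from a TSV
weight table with :func:`load_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "risk_allele", "other_allele", "or"]


class PanelError(ValueError):
    """Malformed or inconsistent weight-table input."""


@dataclass
class RiskPanel:
    """Weight table for a biallelic SNP panel.

    ``entries`` has one row per SNP with columns ``snp_id``, ``chrom``,
    ``pos``, ``risk_allele``, ``other_allele``, ``odds_ratio``, ``weight``
    (= ln(odds_ratio)) and ``hla_flag``.  Row order is the column order of
    any genotype matrix scored against the panel.
    """

    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.entries
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise PanelError(f"duplicate snp_id: {dup!r}")
        if (df["odds_ratio"] <= 0).any():
            bad = df.loc[df["odds_ratio"] <= 0].index[0]
            raise PanelError(f"odds_ratio must be > 0 (row {bad})")
        for col in ("risk_allele", "other_allele"):
            bad = ~df[col].isin(list(VALID_ALLELES))
            if bad.any():
                raise PanelError(
                    f"malformed allele {df.loc[bad, col].iloc[0]!r} in column {col}"
                )
        if (df["risk_allele"] == df["other_allele"]).any():
            raise PanelError("risk_allele must differ from other_allele")
        if not np.allclose(df["weight"], np.log(df["odds_ratio"]), atol=1e-12):
            raise PanelError("weight column inconsistent with ln(odds_ratio)")

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    @property
    def snp_ids(self) -> list[str]:
        return self.entries["snp_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(float)

    def subset(self, snp_ids: list[str]) -> "RiskPanel":
        """Sub-panel restricted to ``snp_ids`` (e.g. the HLA subset)."""
        missing = set(snp_ids) - set(self.snp_ids)
        if missing:
            raise PanelError(f"subset id absent from panel: {sorted(missing)[0]!r}")
        keep = self.entries["snp_id"].isin(snp_ids)
        return RiskPanel(self.entries.loc[keep].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        out = self.entries.rename(columns={"odds_ratio": "or"})[PANEL_COLUMNS]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskPanel":
        df = df.copy()
        if "odds_ratio" not in df.columns:
            df = df.rename(columns={"or": "odds_ratio"})
        if "weight" not in df.columns:
            with np.errstate(invalid="ignore"):
                df["weight"] = np.log(np.where(df["odds_ratio"] > 0,
                                               df["odds_ratio"], np.nan))
            df.loc[df["odds_ratio"] <= 0, "weight"] = 0.0
        if "hla_flag" not in df.columns:
            df["hla_flag"] = False
        df["pos"] = df["pos"].astype(int)
        df["chrom"] = df["chrom"].astype(str)
        return cls(df.reset_index(drop=True))


def load_panel(path) -> RiskPanel:
    """Read a TSV weight table (snp_id chrom pos risk_allele other_allele or).

    Raises :class:`PanelError` naming the offending row/id on duplicate
    SNP ids, non-positive odds ratios or malformed alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"weight table missing columns: {sorted(missing)}")
    if not np.issubdtype(np.asarray(df["or"]).dtype, np.number):
        raise PanelError("or column must be numeric")
    bad = df["or"] <= 0
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1  # 1-based data row
        raise PanelError(f"odds_ratio must be > 0 (row {row} of weight table)")
    return RiskPanel.from_frame(df.rename(columns={"or": "odds_ratio"}))


def estimate_allelic_or(
    genotypes: "GenotypeMatrix",
    status: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP allelic odds ratio from the case/control 2x2 allele table.

    For SNP j the table counts risk and non-risk alleles in cases
    (a, b) and controls (c, d); OR = (a*d)/(b*c).  When any cell is zero,
    the Haldane-Anscombe correction adds 0.5 to all four cells.  The CI is
    Wald on the log scale.

    Parameters
    ----------
    genotypes
        Complete (no missing calls) risk-allele dosage matrix.
    status
        Boolean case indicator, aligned with ``genotypes.individual_ids``.

    Returns
    -------
    DataFrame with columns snp_id, odds_ratio, ci_low, ci_high,
    case_risk/case_other/control_risk/control_other allele counts.
    """
    status = np.asarray(status, bool)
    if status.all() or not status.any():
        raise ValueError("need at least one case and one control")
    dos = genotypes.dosage
    if np.isnan(dos).any():
        raise ValueError("missing dosages present; apply filter_complete first")
    n_case = int(status.sum())
    n_ctrl = int((~status).sum())
    a = dos[status].sum(axis=0)                 # case risk alleles
    b = 2.0 * n_case - a                        # case other alleles
    c = dos[~status].sum(axis=0)                # control risk alleles
    d = 2.0 * n_ctrl - c
    cells = np.stack([a, b, c, d])
    zero = (cells == 0).any(axis=0)
    cells = cells + np.where(zero, 0.5, 0.0)
    a, b, c, d = cells
    log_or = np.log(a * d) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "odds_ratio": np.exp(log_or),
        "ci_low": np.exp(log_or - z * se),
        "ci_high": np.exp(log_or + z * se),
        "case_risk": a, "case_other": b,
        "control_risk": c, "control_other": d,
    })


def panel_from_estimates(template: RiskPanel, estimates: pd.DataFrame) -> RiskPanel:
    """New panel with the template's SNP metadata but estimated odds ratios."""
    df = template.entries[["snp_id", "chrom", "pos", "risk_allele",
                           "other_allele", "hla_flag"]].copy()
    est = estimates.set_index("snp_id")["odds_ratio"]
    df["odds_ratio"] = df["snp_id"].map(est).to_numpy(float)
    return RiskPanel.from_frame(df)
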