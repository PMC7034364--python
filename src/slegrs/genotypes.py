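"""Risk-allele dosage matrices and genotype I/O (VCF / dosage CSV).

Dosages count copies of the panel's declared risk allele (0, 1, 2, or
missing).  VCF records are oriented against the panel: if ALT is the risk
allele the dosage is the ALT count, if REF is the risk allele it is
``2 - ALT count``; records whose allele pair does not match the panel in
either order are rejected (no strand auto-flipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import RiskPanel


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs risk-allele dosage matrix.

    ``dosage`` is float with values in {0, 1, 2} and NaN for missing
    calls; column order matches the panel's entries.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, float)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise GenotypeError("dosage shape does not match ids")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise GenotypeError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def column_index(self, snp_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], int)
        except KeyError as exc:
            raise GenotypeError(f"snp id absent from matrix: {exc.args[0]!r}")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.individual_ids,
                          columns=self.snp_ids)
        df.index.name = "individual_id"
        df.to_csv(path, na_rep="NA")


def filter_complete(genotypes: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Drop every individual with any missing panel call.

    Returns the filtered matrix (input order preserved) and the number of
    individuals removed.  Raises if nobody has a complete genotype.
    """
    keep = ~np.isnan(genotypes.dosage).any(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise GenotypeError("all individuals had missing genotype data")
    if n_removed == 0:
        return genotypes, 0
    ids = [i for i, k in zip(genotypes.individual_ids, keep) if k]
    return GenotypeMatrix(ids, genotypes.snp_ids, genotypes.dosage[keep]), n_removed


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="individual_id", na_values=["NA"])
    return GenotypeMatrix(df.index.astype(str).tolist(),
                          df.columns.tolist(), df.to_numpy(float))


def read_vcf(path, panel: RiskPanel) -> GenotypeMatrix:
    """Read biallelic SNP GT calls from a VCF v4.2 file, panel-oriented.

    Records are matched to panel entries by ID.  A record whose
    (REF, ALT) pair is not the panel's (risk, other) pair in either order
    is rejected with an allele-mismatch report, as are multiallelic
    records.  Panel SNPs absent from the VCF become missing columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    meta = panel.entries.set_index("snp_id")
    cols = {s: np.full(n, np.nan) for s in panel.snp_ids}
    mismatches: list[str] = []
    for rec in vcf:
        sid = rec.ID
        if sid not in cols:
            continue
        if len(rec.ALT) != 1:
            mismatches.append(f"{sid}: multiallelic record")
            continue
        risk = meta.at[sid, "risk_allele"]
        other = meta.at[sid, "other_allele"]
        ref, alt = rec.REF, rec.ALT[0]
        if (ref, alt) == (other, risk):
            flip = False
        elif (ref, alt) == (risk, other):
            flip = True
        else:
            mismatches.append(
                f"{sid}: VCF alleles {ref}/{alt} do not match panel "
                f"{risk}/{other}")
            continue
        gt = np.array(rec.genotypes, object)
        alleles = np.array([[g[0], g[1]] for g in gt], float)
        alleles[alleles < 0] = np.nan  # ./. missing
        alt_count = alleles.sum(axis=1)
        cols[sid] = (2.0 - alt_count) if flip else alt_count
    if mismatches:
        raise GenotypeError("allele-mismatch records: " + "; ".join(mismatches))
    dosage = np.column_stack([cols[s] for s in panel.snp_ids])
    return GenotypeMatrix(samples, panel.snp_ids, dosage)


def write_vcf(path, genotypes: GenotypeMatrix, panel: RiskPanel) -> None:
    """Write dosages as a plain-text VCF v4.2 with GT fields.

    REF is the panel's other allele and ALT the risk allele, so the ALT
    count equals the stored dosage.
    """
    meta = panel.entries.set_index("snp_id")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individual_ids) + "\n")
        order = meta.loc[genotypes.snp_ids].sort_values(["chrom", "pos"])
        col = {s: j for j, s in enumerate(genotypes.snp_ids)}
        for sid, row in order.iterrows():
            calls = [gt_map.get(v, "./.")
                     for v in genotypes.dosage[:, col[sid]]]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{sid}\t"
                     f"{row['other_allele']}\t{row['risk_allele']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")
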