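"""Reading, harmonization, QC and rescaling of GWAS summary statistics.

A summary-statistics table is a :class:`pandas.DataFrame` with the canonical
columns ``snp, chr, bp, a1, a2, freq, beta, se, z, p, n`` (a subset may be
absent depending on the source file). ``a1`` is the effect allele; ``beta``
is the per-allele effect on the standardized phenotype scale; ``n`` is the
per-SNP sample size, with effective N substituted for case-control designs.

Coordinates are 1-based inclusive throughout, matching GWAS convention.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDesign",
    "read_sumstats",
    "read_reference_panel",
    "write_sumstats",
    "qc_filter",
    "harmonize",
    "phenotype_scale",
    "rescale_to_standardized",
    "effective_n",
]

#: default header-name synonyms, upper-cased for matching
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "snp": ("SNP", "RSID", "MARKERNAME", "ID"),
    "chr": ("CHR", "CHROM", "CHROMOSOME"),
    "bp": ("BP", "POS", "POSITION"),
    "a1": ("A1", "EFFECT_ALLELE", "ALLELE1", "EA"),
    "a2": ("A2", "OTHER_ALLELE", "ALLELE2", "OA", "NEA"),
    "freq": ("FRQ", "MAF", "FREQ", "EAF", "FREQ_A1", "AF1"),
    "beta": ("BETA", "B", "EFFECT"),
    "se": ("SE", "STDERR"),
    "z": ("Z", "ZSCORE", "Z_STAT"),
    "p": ("P", "PVAL", "P_VALUE", "PVALUE"),
    "n": ("N", "NEFF", "N_EFF"),
    "n_cas": ("N_CAS", "NCASE", "N_CASES", "NCAS"),
    "n_con": ("N_CON", "NCONTROL", "N_CONTROLS", "NCON"),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class CohortDesign:
    """Case/control composition of one contributing cohort."""

    label: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(
                f"cohort {self.label!r}: case and control counts must be "
                f"positive (got {self.n_cases}/{self.n_controls})"
            )

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_ratio(self) -> float:
        return self.n_cases / self.n_total

    @property
    def n_effective(self) -> float:
        """4*v*(1-v)*n: the balanced-design sample size of equal power."""
        v = self.case_ratio
        return 4.0 * v * (1.0 - v) * self.n_total


def effective_n(designs: Iterable[CohortDesign]) -> float:
    """Total effective sample size, summed over cohorts.

    Each cohort contributes 4*v*(1-v)*n where v is its case ratio, so a
    balanced cohort contributes its full n and imbalance discounts it.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("at least one cohort design required")
    return float(sum(d.n_effective for d in designs))


def _resolve_columns(header: list[str], column_map: Mapping[str, str] | None
                     ) -> dict[str, str]:
    """Map canonical names to actual file columns."""
    resolved: dict[str, str] = {}
    upper = {h.upper(): h for h in header}
    explicit = {k.lower(): v for k, v in (column_map or {}).items()}
    for canon, synonyms in DEFAULT_COLUMN_MAP.items():
        if canon in explicit:
            name = explicit[canon]
            if name not in header:
                raise ValueError(f"mapped column {name!r} for {canon!r} not in file header")
            resolved[canon] = name
            continue
        for syn in synonyms:
            if syn in upper:
                resolved[canon] = upper[syn]
                break
    return resolved


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited sumstats file into the canonical table.

    The file must provide SNP ids, both alleles, and at least one of
    (beta, se) or z. Missing z is derived as beta/se; missing p as the
    two-sided normal tail of z. Rows with unparsable or missing required
    values are dropped and counted in ``table.attrs['qc']``.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    cols = _resolve_columns(list(raw.columns), column_map)
    for required in ("snp", "a1", "a2"):
        if required not in cols:
            raise ValueError(f"missing required column: {required!r}")
    if "z" not in cols and not ("beta" in cols and "se" in cols):
        raise ValueError("missing required column: need 'z' or both 'beta' and 'se'")

    table = pd.DataFrame({canon: raw[actual] for canon, actual in cols.items()})
    n_in = len(table)
    table["snp"] = table["snp"].astype(str)
    for al in ("a1", "a2"):
        table[al] = table[al].str.upper().str.strip()
    numeric = [c for c in ("chr", "bp", "freq", "beta", "se", "z", "p", "n",
                           "n_cas", "n_con") if c in table.columns]
    for c in numeric:
        table[c] = pd.to_numeric(table[c], errors="coerce")

    required_numeric = ["beta", "se"] if "beta" in table.columns else ["z"]
    keep = table["snp"].notna() & table[required_numeric].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    table = table.loc[keep].reset_index(drop=True)

    if "z" not in table.columns:
        table["z"] = table["beta"] / table["se"]
    if "p" not in table.columns:
        from scipy.stats import norm
        table["p"] = 2.0 * norm.sf(np.abs(table["z"]))
    if "n" not in table.columns and {"n_cas", "n_con"} <= set(table.columns):
        v = table["n_cas"] / (table["n_cas"] + table["n_con"])
        table["n"] = 4.0 * v * (1.0 - v) * (table["n_cas"] + table["n_con"])
    table = table.drop(columns=[c for c in ("n_cas", "n_con") if c in table.columns])

    dupes = int(table["snp"].duplicated().sum())
    if dupes:
        table = table.drop_duplicates("snp", keep="first").reset_index(drop=True)
    table.attrs["qc"] = {"rows_in": n_in, "rows_dropped_missing": n_dropped,
                         "rows_dropped_duplicate": dupes}
    if n_dropped or dupes:
        logger.info("read_sumstats: dropped %d missing/unparsable and %d duplicate rows",
                    n_dropped, dupes)
    return table


def read_reference_panel(path) -> pd.DataFrame:
    """Read a reference panel table (snp, chr, bp, a1, a2, maf)."""
    panel = pd.read_csv(path, sep=r"\s+")
    panel.columns = [c.lower() for c in panel.columns]
    rename = {"ref_a1": "a1", "ref_a2": "a2", "pos": "bp", "chrom": "chr"}
    panel = panel.rename(columns=rename)
    for required in ("snp", "a1", "a2", "maf"):
        if required not in panel.columns:
            raise ValueError(f"reference panel missing column: {required!r}")
    if panel["snp"].duplicated().any():
        raise ValueError("reference panel has duplicate SNP ids")
    return panel


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write a canonical table as tab-delimited text (gzip if *.gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def qc_filter(table: pd.DataFrame, maf_min: float = 0.01,
              chisq_max: float | None = 80.0) -> pd.DataFrame:
    """Pre-LDSC quality filters.

    Drops non-ACGT alleles (indels, multi-allelic codes), SNPs with
    MAF below ``maf_min`` and, unless disabled, SNPs with chi-square above
    ``chisq_max`` (implausibly strong hits that destabilize the regression).
    """
    report = dict(table.attrs.get("qc", {}))
    n0 = len(table)
    acgt = table["a1"].isin(_VALID_ALLELES) & table["a2"].isin(_VALID_ALLELES) \
        & (table["a1"] != table["a2"])
    table = table.loc[acgt]
    report["dropped_non_acgt"] = n0 - len(table)
    if "freq" in table.columns and maf_min is not None:
        n1 = len(table)
        maf = np.minimum(table["freq"], 1.0 - table["freq"])
        table = table.loc[maf >= maf_min]
        report["dropped_maf"] = n1 - len(table)
    if chisq_max is not None:
        n2 = len(table)
        table = table.loc[table["z"] ** 2 <= chisq_max]
        report["dropped_chisq"] = n2 - len(table)
    out = table.reset_index(drop=True)
    out.attrs["qc"] = report
    return out


def harmonize(table: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Align a sumstats table to a reference allele frame.

    SNPs are restricted to the panel. A SNP whose alleles are the swap of
    the panel's (a1, a2) has its effect sign flipped and alleles swapped into
    the panel frame. Strand-ambiguous SNPs (A/T or C/G) with effect-allele
    frequency in [0.40, 0.60] are removed, as are SNPs whose alleles match
    neither panel orientation. Removal counts land in ``attrs['qc']``.
    """
    if table.empty or panel.empty:
        raise ValueError("harmonize requires nonempty table and panel")
    report = dict(table.attrs.get("qc", {}))
    merged = table.merge(
        panel[["snp", "a1", "a2"]].rename(columns={"a1": "ref_a1", "a2": "ref_a2"}),
        on="snp", how="inner")
    report["dropped_not_in_panel"] = len(table) - len(merged)
    if merged.empty:
        raise ValueError("no SNPs shared with the reference panel")

    ambiguous = merged["a1"].map(_COMPLEMENT) == merged["a2"]
    if "freq" in merged.columns:
        freq = merged["freq"].to_numpy(dtype=float)
        mid_freq = (freq >= 0.40) & (freq <= 0.60)
        drop_ambig = ambiguous & (mid_freq | np.isnan(freq))
    else:
        drop_ambig = ambiguous
    merged = merged.loc[~drop_ambig]
    report["dropped_ambiguous"] = int(drop_ambig.sum())

    match = (merged["a1"] == merged["ref_a1"]) & (merged["a2"] == merged["ref_a2"])
    swap = (merged["a1"] == merged["ref_a2"]) & (merged["a2"] == merged["ref_a1"])
    report["dropped_mismatch"] = int((~match & ~swap).sum())
    merged = merged.loc[match | swap].copy()
    if merged.empty:
        raise ValueError("no SNPs left after allele matching")

    flip = (merged["a1"] == merged["ref_a2"]).to_numpy()
    for col in ("beta", "z"):
        if col in merged.columns:
            merged.loc[flip, col] = -merged.loc[flip, col]
    if "freq" in merged.columns:
        merged.loc[flip, "freq"] = 1.0 - merged.loc[flip, "freq"]
    merged["a1"] = merged["ref_a1"]
    merged["a2"] = merged["ref_a2"]
    out = merged.drop(columns=["ref_a1", "ref_a2"]).reset_index(drop=True)
    out.attrs["qc"] = report
    logger.info("harmonize: %d SNPs retained (%d flipped to panel frame)",
                len(out), int(flip.sum()))
    return out


def phenotype_scale(table: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-SNP implied phenotypic SD and its median.

    For SNP j with allele frequency p_j, genotype variance under
    Hardy-Weinberg is var_x = 2 p_j (1 - p_j) and

        sd_y,j = sqrt(var_x * (n_j * se_j^2 + beta_j^2)),

    the exact relation for least squares on a standardized phenotype. A
    median far from 1 signals an unstandardized phenotype scale.
    """
    for col in ("beta", "se", "freq", "n"):
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"phenotype_scale requires complete column {col!r}")
    p = table["freq"].to_numpy(dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequency of 0 or 1: zero genotype variance")
    var_x = 2.0 * p * (1.0 - p)
    sd_y = np.sqrt(var_x * (table["n"].to_numpy(float) * table["se"].to_numpy(float) ** 2
                            + table["beta"].to_numpy(float) ** 2))
    return sd_y, float(np.median(sd_y))


def rescale_to_standardized(table: pd.DataFrame, tolerance: float = 0.05
                            ) -> tuple[pd.DataFrame, bool]:
    """Divide beta and se by the median implied SD when it departs from 1.

    z and p are scale-free and left untouched. Returns the (possibly
    rescaled) table and whether rescaling occurred. Idempotent: a table on
    the standardized scale passes through unchanged.
    """
    _, med = phenotype_scale(table)
    if abs(med - 1.0) <= tolerance:
        return table, False
    out = table.copy()
    out["beta"] = out["beta"] / med
    out["se"] = out["se"] / med
    out.attrs = dict(table.attrs)
    out.attrs["sdy_median"] = med
    logger.info("rescale_to_standardized: divided beta/se by median sd_y = %.4f", med)
    return out, True
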