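"""Locus definition from association results and an LD reference.

Implements the FUMA-style two-stage rule: greedy selection of independent
significant SNPs by ascending p-value under an r-squared ceiling, merging of
independent SNPs into loci by physical proximity, expansion with candidate
SNPs in LD regardless of their own significance, and cross-trait overlap
through shared candidate SNPs.

Internal coordinates are 1-based inclusive; the BED export converts to
0-based half-open (start_bed = start - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LdMatrix", "Locus", "clump", "candidate_snps",
           "cross_trait_overlap", "loci_table", "write_bed"]


@dataclass
class LdMatrix:
    """Pairwise signed LD correlations for an ordered SNP panel."""

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match SNP count")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.abs(self.r).max() > 1.0 + 1e-8:
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index_of(self, snp: str) -> int | None:
        return self._index.get(snp)

    def r2(self, i: int, j: int) -> float:
        return float(self.r[i, j] ** 2)


@dataclass
class Locus:
    """A genomic interval anchored by independent significant SNPs."""

    chrom: int
    start: int
    end: int
    lead_snp: str
    independent_snps: list[str]
    candidate_snps: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must not exceed end")
        if self.lead_snp not in self.independent_snps:
            raise ValueError("lead SNP must be among the independent SNPs")


def _sort_key(results: pd.DataFrame) -> pd.DataFrame:
    # ascending p; ties broken by chromosome, position, then SNP id so the
    # greedy pass is invariant to input row order
    return results.sort_values(["p", "chr", "bp", "snp"], kind="mergesort")


def clump(results: pd.DataFrame, ld: LdMatrix, p_threshold: float = 5e-8,
          r2_independent: float = 0.1, window: int = 250_000) -> list[Locus]:
    """Greedy clumping of significant SNPs into independent loci.

    Significant SNPs (p < ``p_threshold``) are visited in ascending p; a SNP
    joins the independent set iff its r-squared with every previously
    accepted independent SNP is below ``r2_independent``. Rejected SNPs are
    assigned to the accepted SNP they are linked to. Independent SNPs on the
    same chromosome within ``window`` bp of each other are merged into one
    locus (chained), with the lowest-p member as lead.
    """
    sig = results.loc[results["p"] < p_threshold]
    if sig.empty:
        return []
    sig = _sort_key(sig)

    accepted: list[dict] = []  # each: snp, chr, bp, p, members (snp ids)
    for row in sig.itertuples(index=False):
        idx = ld.index_of(row.snp)
        if idx is None:
            logger.warning("clump: SNP %s absent from LD reference, excluded", row.snp)
            continue
        linked_to = None
        for acc in accepted:
            if ld.r2(idx, acc["idx"]) >= r2_independent:
                linked_to = acc
                break
        if linked_to is None:
            accepted.append({"snp": row.snp, "idx": idx, "chr": int(row.chr),
                             "bp": int(row.bp), "p": float(row.p),
                             "members": [(row.snp, int(row.bp))]})
        else:
            linked_to["members"].append((row.snp, int(row.bp)))

    # merge independent SNPs by proximity (chained within `window`)
    accepted.sort(key=lambda a: (a["chr"], a["bp"], a["snp"]))
    loci: list[Locus] = []
    group: list[dict] = []

    def _flush(group: list[dict]) -> None:
        if not group:
            return
        members = [m for acc in group for m in acc["members"]]
        ind = sorted({acc["snp"] for acc in group})
        lead = min(group, key=lambda a: (a["p"], a["chr"], a["bp"], a["snp"]))
        positions = [bp for _, bp in members]
        loci.append(Locus(chrom=group[0]["chr"], start=min(positions),
                          end=max(positions), lead_snp=lead["snp"],
                          independent_snps=ind,
                          candidate_snps={s for s, _ in members}))

    for acc in accepted:
        if group and acc["chr"] == group[-1]["chr"] \
                and acc["bp"] - group[-1]["bp"] <= window:
            group.append(acc)
        else:
            _flush(group)
            group = [acc]
    _flush(group)
    return loci


def candidate_snps(loci: list[Locus], results: pd.DataFrame, ld: LdMatrix,
                   r2_candidate: float = 0.6, use_signed_r: bool = False
                   ) -> list[Locus]:
    """Attach candidate SNPs to each locus and extend its bounds.

    Every panel SNP with r-squared at or above ``r2_candidate`` (or |r|
    above it when ``use_signed_r``) to any independent significant SNP of a
    locus joins that locus's candidate set, irrespective of its own p-value.
    """
    pos_by_snp = dict(zip(ld.snp_ids, ld.pos))
    for locus in loci:
        ind_idx = [ld.index_of(s) for s in locus.independent_snps]
        ind_idx = [i for i in ind_idx if i is not None]
        if not ind_idx:
            continue
        r_block = ld.r[np.asarray(ind_idx)]
        if use_signed_r:
            linked = np.abs(r_block) > r2_candidate
        else:
            linked = r_block ** 2 >= r2_candidate
        hits = np.flatnonzero(linked.any(axis=0))
        same_chrom = ld.chrom[hits] == locus.chrom
        for i in hits[same_chrom]:
            locus.candidate_snps.add(ld.snp_ids[int(i)])
        member_pos = [int(pos_by_snp[s]) for s in locus.candidate_snps
                      if s in pos_by_snp]
        if member_pos:
            locus.start = min(locus.start, min(member_pos))
            locus.end = max(locus.end, max(member_pos))
    return loci


def cross_trait_overlap(loci_a: list[Locus], loci_b: list[Locus]
                        ) -> dict[str, object]:
    """Locus overlap between two traits via shared candidate SNPs.

    Two loci overlap iff their candidate-SNP sets intersect, so a shared
    linked (even non-significant) SNP suffices. Returns the overlap pairs
    (index_a, index_b) and the per-trait loci with no counterpart.
    """
    pairs: list[tuple[int, int]] = []
    for i, la in enumerate(loci_a):
        for j, lb in enumerate(loci_b):
            if la.candidate_snps & lb.candidate_snps:
                pairs.append((i, j))
    hit_a = {i for i, _ in pairs}
    hit_b = {j for _, j in pairs}
    return {
        "pairs": pairs,
        "novel_a": [i for i in range(len(loci_a)) if i not in hit_a],
        "novel_b": [j for j in range(len(loci_b)) if j not in hit_b],
    }


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Tabular locus summary (CHR, START, END, LEAD_SNP, counts)."""
    return pd.DataFrame({
        "CHR": [l.chrom for l in loci],
        "START": [l.start for l in loci],
        "END": [l.end for l in loci],
        "LEAD_SNP": [l.lead_snp for l in loci],
        "N_IND_SIG": [len(l.independent_snps) for l in loci],
        "N_CANDIDATES": [len(l.candidate_snps) for l in loci],
    })


def write_bed(loci: list[Locus], path) -> None:
    """Write loci as BED: 0-based half-open, start_bed = start - 1."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead_snp}\n")
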