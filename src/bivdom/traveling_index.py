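"""RNA polymerase II traveling index (TI): the ratio of RNAPII density in a
promoter bin (1 kb window centered on the TSS) to density in the gene body
(the remainder of the gene extending to the TES).

A TI near 1 indicates promoter clearance keeping pace with initiation; TI > 2
indicates promoter-proximal pausing dominance. Cohorts of genes are compared
by ECDFs of their TI, the two-sample KS test, and the fraction of genes with
TI above a pausing threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import GeneModel, TagCollection
from .stats import Ecdf, KsResult, ks_two_sample

TI_COLUMNS = ["gene_id", "promoter_density", "body_density", "ti",
              "included", "exclusion_reason"]


@dataclass(frozen=True)
class TravelingIndexParams:
    promoter_halfwidth: int = 500   # promoter bin = [TSS - h, TSS + h)
    min_body_length: int = 1000
    ti_threshold: float = 2.0
    min_promoter_tags: int = 1      # "marked by RNAPII" inclusion rule

    def __post_init__(self):
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        if self.ti_threshold <= 0:
            raise ValueError("ti_threshold must be positive")


def _rpbm(count: int, length: int, library_size: int) -> float:
    return count * 1e6 / (length * library_size)


def gene_ti(tags: TagCollection, gene: GeneModel,
            params: TravelingIndexParams = TravelingIndexParams()) -> dict:
    """One TI table row; exclusions are data (flag + reason), not errors.

    The promoter bin is [TSS - h, TSS + h) in genomic coordinates; the body is
    the remainder of the gene span from the promoter-bin edge toward the TES.
    """
    h = params.promoter_halfwidth
    prom_start, prom_end = gene.tss - h, gene.tss + h
    if gene.strand == "+":
        body_start, body_end = gene.tss + h, gene.tes
    else:
        body_start, body_end = gene.tes, gene.tss - h
    body_len = max(body_end - body_start, 0)

    row = {"gene_id": gene.gene_id, "promoter_density": 0.0, "body_density": 0.0,
           "ti": float("nan"), "included": False, "exclusion_reason": ""}
    prom_count = tags.count_in(gene.chrom, max(prom_start, 0), prom_end)
    row["promoter_density"] = _rpbm(prom_count, prom_end - max(prom_start, 0),
                                    tags.library_size)
    if body_len < params.min_body_length:
        row["exclusion_reason"] = "short body"
        return row
    body_count = tags.count_in(gene.chrom, body_start, body_end)
    row["body_density"] = _rpbm(body_count, body_len, tags.library_size)
    if prom_count < params.min_promoter_tags:
        row["exclusion_reason"] = "no promoter signal"
        return row
    if body_count == 0:
        row["exclusion_reason"] = "zero body density"
        return row
    row["ti"] = row["promoter_density"] / row["body_density"]
    row["included"] = True
    return row


def ti_table(tags: TagCollection, genes: list[GeneModel],
             params: TravelingIndexParams = TravelingIndexParams()) -> pd.DataFrame:
    return pd.DataFrame([gene_ti(tags, g, params) for g in genes],
                        columns=TI_COLUMNS)


@dataclass
class TiComparison:
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    ecdf_a: Ecdf
    ecdf_b: Ecdf
    ks: KsResult
    fraction_above_a: float   # fraction of included genes with TI > threshold
    fraction_above_b: float


def ti_cohort_compare(tags: TagCollection, cohort_a: list[GeneModel],
                      cohort_b: list[GeneModel],
                      params: TravelingIndexParams = TravelingIndexParams(),
                      min_included: int = 20) -> TiComparison:
    """Compare two gene cohorts' TI distributions (ECDF, KS, fraction above
    the pausing threshold). Fractions use strict inequality (TI > threshold)."""
    tables = []
    for name, cohort in (("a", cohort_a), ("b", cohort_b)):
        tab = ti_table(tags, cohort, params)
        included = tab[tab["included"]]
        if len(included) < min_included:
            raise ValueError(
                f"cohort {name} has only {len(included)} included genes "
                f"(minimum {min_included})")
        tables.append(tab)
    ti_a = tables[0].loc[tables[0]["included"], "ti"].to_numpy()
    ti_b = tables[1].loc[tables[1]["included"], "ti"].to_numpy()
    return TiComparison(
        table_a=tables[0], table_b=tables[1],
        ecdf_a=Ecdf(ti_a), ecdf_b=Ecdf(ti_b),
        ks=ks_two_sample(ti_a, ti_b),
        fraction_above_a=float((ti_a > params.ti_threshold).mean()),
        fraction_above_b=float((ti_b > params.ti_threshold).mean()),
    )
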