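"""Hotspot tabulation and localized indel-process diagnostics.

Hotspots are single positions mutated in many distinct patients; the
2-5-bp indel tests flag genes whose indel size spectrum or indel rate
departs from the cohort background, a hallmark of transcription-
associated mutagenesis rather than positive selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Element, MutationRecord, ParameterError
from .stats import benjamini_hochberg, binom_sf

INDEL_SIZE_MIN = 2
INDEL_SIZE_MAX = 5  # inclusive on both ends


def find_hotspots(mutations: Sequence[MutationRecord], top_k: Optional[int] = 50,
                  min_fraction: Optional[float] = None,
                  cohort_size: Optional[int] = None) -> pd.DataFrame:
    """Rank SNV positions by the number of distinct mutated patients.

    Ties are broken by genome order (chrom, pos, alt).  Either the top
    ``top_k`` positions or all positions mutated in at least
    ``min_fraction`` of ``cohort_size`` patients are returned.
    """
    snvs = [m for m in mutations if m.var_type == "SNV"]
    patients: dict[tuple, set] = {}
    for m in snvs:
        patients.setdefault((m.chrom, m.pos, m.ref, m.alt), set()).add(m.sample_id)
    if cohort_size is None:
        cohort_size = len({m.sample_id for m in snvs}) or 1
    rows = [dict(chrom=c, pos=p, ref=r, alt=a, n_patients=len(ss),
                 patient_fraction=len(ss) / cohort_size)
            for (c, p, r, a), ss in patients.items()]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "n_patients", "patient_fraction"])
    if df.empty:
        return df
    df = df.sort_values(["n_patients", "chrom", "pos", "alt"],
                        ascending=[False, True, True, True],
                        kind="mergesort").reset_index(drop=True)
    if min_fraction is not None:
        return df[df["patient_fraction"] >= min_fraction].reset_index(drop=True)
    return df.head(top_k).reset_index(drop=True)


def _is_2to5(m: MutationRecord) -> bool:
    return m.var_type in ("INS", "DEL") and \
        INDEL_SIZE_MIN <= m.indel_length <= INDEL_SIZE_MAX


def indel_size_enrichment(indels_by_gene: dict[str, Sequence[MutationRecord]],
                          background_proportion: Optional[float] = None
                          ) -> pd.DataFrame:
    """Per-gene enrichment of 2-5-bp indels against the background proportion.

    One-sided binomial test: p = P(X >= observed 2-5-bp count) given the
    gene's total indel count and the background proportion of 2-5-bp
    indels.  When no background is supplied it is computed from all
    other genes' indels (leave-one-out).  Genes with zero indels are not
    evaluable and flagged.  BH within this test family.
    """
    totals = {g: len(list(ms)) for g, ms in indels_by_gene.items()}
    hits = {g: sum(_is_2to5(m) for m in ms) for g, ms in indels_by_gene.items()}
    all_total = sum(totals.values())
    all_hits = sum(hits.values())
    rows = []
    for g in indels_by_gene:
        n, k = totals[g], hits[g]
        if background_proportion is None:
            denom = all_total - n
            bg = (all_hits - k) / denom if denom > 0 else np.nan
        else:
            bg = background_proportion
        if n == 0 or not np.isfinite(bg) or not (0 < bg < 1):
            rows.append(dict(gene=g, n_indels=n, n_2to5=k,
                             background_proportion=bg, p=np.nan,
                             evaluable=False))
        else:
            rows.append(dict(gene=g, n_indels=n, n_2to5=k,
                             background_proportion=bg,
                             p=float(binom_sf(k, n, bg)), evaluable=True))
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    ok = df["evaluable"]
    if ok.any():
        df.loc[ok, "q"] = benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    df["enriched"] = ok & (df["q"] < 0.1)
    return df


def indel_rate_test(counts_by_gene: dict[str, int],
                    lengths_by_gene: dict[str, int]) -> pd.DataFrame:
    """Per-gene excess indel rate against a length-scaled expectation.

    Each gene's indel count is compared to a binomial draw of the cohort
    total with success probability length_gene / total length (the
    uniform-rate null); one-sided upper tail, BH within this family.
    """
    genes = list(counts_by_gene)
    total_count = sum(counts_by_gene.values())
    total_length = sum(lengths_by_gene[g] for g in genes)
    if total_length <= 0:
        raise ParameterError("total gene length must be positive")
    rows = []
    for g in genes:
        k = counts_by_gene[g]
        p0 = lengths_by_gene[g] / total_length
        p = float(binom_sf(k, total_count, p0)) if total_count > 0 else 1.0
        rows.append(dict(gene=g, n_indels=k, length=lengths_by_gene[g],
                         expected=total_count * p0, p=p))
    df = pd.DataFrame(rows)
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["elevated"] = df["q"] < 0.1
    return df


def group_indels_by_element(mutations: Sequence[MutationRecord],
                            elements: Sequence[Element]
                            ) -> dict[str, list[MutationRecord]]:
    indels = [m for m in mutations if m.var_type in ("INS", "DEL")]
    return {el.id: [m for m in indels if el.contains(m.chrom, m.pos)]
            for el in elements}
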