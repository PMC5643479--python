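"""Metagenome content inferred from 16S profiles of labeled taxa.

Reproduces the PICRUSt-style arithmetic on user-supplied reference
tables: 16S copy-number correction of the count table, restriction to
isotope-labeled families, KO (KEGG Ortholog) profile prediction as the
abundance x gene-count cross product, and KO enrichment in dense labeled
pooled fractions computed with the same share-difference formula as
taxon activity.  The reference content (copy numbers per taxon, gene
counts per taxon x KO) is an input; no reference database is bundled.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import CountTable, parse_lineage, RANKS

__all__ = [
    "copy_number_normalize",
    "filter_to_labeled_taxa",
    "predict_ko_profile",
    "ko_shares",
    "ko_enrichment",
    "ko_heatmap_matrix",
]


def copy_number_normalize(
    table: CountTable,
    copy_numbers: Mapping[str, float] | pd.Series,
    default: float | None = None,
) -> CountTable:
    """Divide each taxon's counts by its 16S rRNA gene copy number.

    Multi-copy 16S operons inflate amplicon counts; dividing by the
    per-taxon copy number converts sequence counts to (relative) genome
    abundances.  Taxa missing from the reference use ``default`` if
    given, otherwise raise.
    """
    ref = pd.Series(copy_numbers, dtype=float)
    if (ref < 1).any():
        bad = ref.index[ref < 1].tolist()
        raise ValueError(f"copy numbers below 1 for: {bad}")
    cn = ref.reindex(table.taxa)
    if cn.isna().any():
        if default is None:
            missing = cn.index[cn.isna()].tolist()
            raise ValueError(
                f"no copy number for taxa {missing} and no default configured"
            )
        cn = cn.fillna(float(default))
    corrected = table.counts.div(cn, axis=0)
    return CountTable(corrected, table.lineages, integral=False)


def filter_to_labeled_taxa(
    table: CountTable,
    labeled_taxa: Sequence[str],
    rank: str | None = "family",
) -> tuple[CountTable, pd.DataFrame]:
    """Keep only rows belonging to isotope-labeled taxa.

    ``labeled_taxa`` names values at ``rank`` (default family, matching
    the practice of filtering non-labeled families out of the OTU table
    before metagenome prediction); with ``rank=None`` the names are row
    identifiers.  Returns the filtered table and a report of removed
    rows with their per-sample totals.
    """
    if not len(labeled_taxa):
        raise ValueError("labeled_taxa is empty")
    wanted = set(labeled_taxa)
    if rank is None:
        keep = table.taxa.isin(wanted)
    else:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        values = [
            parse_lineage(lin).get(rank, "") if lin else ""
            for lin in table.lineages
        ]
        keep = np.array([v in wanted for v in values])
    if not keep.any():
        raise ValueError("filter removes every row of the table")
    removed = table.counts.loc[~keep]
    report = removed.assign(total=removed.sum(axis=1)).reset_index(
        names=["taxon"]
    )
    filtered = CountTable(
        table.counts.loc[keep], table.lineages.loc[keep], integral=table.integral
    )
    return filtered, report


def predict_ko_profile(
    corrected: CountTable | pd.DataFrame, ko_reference: pd.DataFrame
) -> pd.DataFrame:
    """Predicted KO abundance per sample: sum over taxa of
    abundance(taxon, sample) x gene_count(taxon, KO).

    ``ko_reference`` is taxon x KO gene counts; missing taxon/KO cells
    count as zero gene copies.  Raises if the reference shares no taxa
    with the table.
    """
    abundance = corrected.counts if isinstance(corrected, CountTable) else corrected
    if (ko_reference.to_numpy() < 0).any():
        raise ValueError("negative gene counts in KO reference")
    shared = abundance.index.intersection(ko_reference.index)
    if shared.empty:
        raise ValueError("no taxa shared between abundance table and KO reference")
    genes = ko_reference.reindex(abundance.index, fill_value=0.0).astype(float)
    return genes.T @ abundance


def ko_shares(profile: pd.DataFrame, ko_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Percent share of each KO within a sample's total KO abundance.

    With ``ko_subset`` the denominator is the curated subset (e.g. a
    lignocellulose-digestion or nitrogen-metabolism KO list); otherwise
    all KOs in the profile.
    """
    if ko_subset is not None:
        missing = [k for k in ko_subset if k not in profile.index]
        if missing:
            raise ValueError(f"KOs absent from profile: {missing}")
        profile = profile.loc[list(ko_subset)]
    totals = profile.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {zero.index.tolist()}")
    return profile.div(totals, axis=1) * 100.0


def ko_enrichment(
    labeled_profile: pd.DataFrame,
    control_profile: pd.DataFrame,
    dense_pools: Sequence[str],
    ko_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """KO enrichment in dense labeled pooled fractions.

    Same formula as taxon activity, applied to KO shares: the KO's
    percent share in the labeled pooled fraction minus its share in the
    control one.  Returns one row per (KO, dense pool).
    """
    if not dense_pools:
        raise ValueError("no dense pooled fractions given")
    if set(labeled_profile.index) != set(control_profile.index):
        raise ValueError("labeled and control profiles must share the same KO set")
    for name, prof in (("labeled", labeled_profile), ("control", control_profile)):
        missing = [p for p in dense_pools if p not in prof.columns]
        if missing:
            raise ValueError(f"{name} profile lacks pooled fraction(s) {missing}")
    lab = ko_shares(labeled_profile, ko_subset)
    ctl = ko_shares(control_profile, ko_subset).reindex(lab.index)
    rows = []
    for pool in dense_pools:
        diff = lab[pool] - ctl[pool]
        for ko, value in diff.items():
            rows.append({"ko": ko, "pool": pool, "enrichment": float(value)})
    return pd.DataFrame(rows)


def ko_heatmap_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """KO x dense-pool matrix of enrichment values."""
    if enrichment.empty:
        raise ValueError("no enrichment records")
    if enrichment.duplicated(subset=["ko", "pool"]).any():
        raise ValueError("duplicate (ko, pool) records")
    return enrichment.pivot(index="ko", columns="pool", values="enrichment")
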