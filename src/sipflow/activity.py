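"""Per-taxon activity in dense pooled fractions of a SIP experiment.

The activity A of a taxon in a dense pooled fraction is its relative
abundance (percent of total sequences) in that pooled fraction of the
labeled gradient minus the same quantity in the control gradient:

    A = 100 * tNS_labeled / NS_labeled - 100 * tNS_control / NS_control

where tNS is the taxon's sequence count in the pooled fraction and NS
the pooled fraction's total.  A > 0 means enrichment in the labeled
dense fraction — the signature of heavy-isotope incorporation; A < 0 is
underrepresentation.  Significance of each enrichment is assessed with a
two-sided Fisher exact test on the 2x2 sequence-count table, adjusted
for multiple testing by Benjamini-Hochberg FDR across taxa within each
dense pooled fraction, and reported in tiers (p<0.01, p<0.05, p<0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RANKS",
    "CountTable",
    "parse_lineage",
    "relative_abundance",
    "fisher_enrichment_p",
    "bh_fdr",
    "significance_tier",
    "compute_activity",
    "collapse_rank",
    "activity_heatmap_matrix",
    "rank_by_activity",
]

#: Recognized taxonomy ranks, root-first, with their QIIME-style prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = dict(zip("kpcofgs", RANKS))


def parse_lineage(text: str) -> dict[str, str]:
    """Parse a semicolon-separated lineage into rank -> name.

    Accepts QIIME-style prefixed fields (``k__Bacteria; f__Lachnospiraceae``)
    and plain root-first paths (``Bacteria;...;Lachnospiraceae``).  Empty
    fields (``f__``) are omitted from the result.
    """
    fields = [f.strip() for f in text.split(";") if f.strip()]
    out: dict[str, str] = {}
    for i, fld in enumerate(fields):
        if len(fld) >= 3 and fld[1:3] == "__" and fld[0] in _PREFIXES:
            name = fld[3:].strip()
            if name:
                out[_PREFIXES[fld[0]]] = name
        elif i < len(RANKS):
            out[RANKS[i]] = fld
        else:
            raise ValueError(f"cannot parse lineage field {fld!r} in {text!r}")
    return out


class CountTable:
    """Taxon-by-sample sequence counts with taxonomy lineages.

    Rows are taxa (OTUs or collapsed higher ranks), columns are samples
    — here, pooled fractions of one gradient.  Counts are non-negative
    integers unless ``integral=False`` (copy-number-corrected abundances
    are real-valued).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        lineages: pd.Series | Mapping[str, str] | None = None,
        integral: bool = True,
    ) -> None:
        counts = pd.DataFrame(counts).copy()
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if integral:
            arr = counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(float)
        counts.index.name = None
        counts.columns.name = None
        self.counts = counts
        if lineages is None:
            lineages = pd.Series("", index=counts.index, name="taxonomy")
        else:
            lineages = pd.Series(lineages, name="taxonomy").reindex(counts.index)
            if lineages.isna().any():
                missing = lineages.index[lineages.isna()].tolist()
                raise ValueError(f"taxa without lineage: {missing}")
            lineages.index.name = None
        for taxon, lin in lineages.items():
            if lin:
                parse_lineage(lin)  # raises on malformed lineages
        self.lineages = lineages
        self.integral = integral

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_totals(self) -> pd.Series:
        """NS: total sequences per sample."""
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountTable)
            and self.counts.equals(other.counts)
            and self.lineages.equals(other.lineages)
        )


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Percent-of-total-sequences normalization, correcting for library size.

    Every column of the result sums to 100.
    """
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {zero.index.tolist()}")
    return table.counts.div(totals, axis=1) * 100.0


def fisher_enrichment_p(
    tns_labeled: int, ns_labeled: int, tns_control: int, ns_control: int
) -> float:
    """Two-sided Fisher exact p for differential representation of a taxon.

    The 2x2 table is [[tNS_lab, NS_lab - tNS_lab], [tNS_ctl, NS_ctl -
    tNS_ctl]]; the p-value sums hypergeometric probabilities of tables at
    most as probable as the observed one.
    """
    cells = (tns_labeled, ns_labeled, tns_control, ns_control)
    if any(c < 0 for c in cells):
        raise ValueError(f"negative count in {cells}")
    if tns_labeled > ns_labeled or tns_control > ns_control:
        raise ValueError("taxon count exceeds sample total")
    table = [
        [tns_labeled, ns_labeled - tns_labeled],
        [tns_control, ns_control - tns_control],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tier(
    value: float, thresholds: tuple[float, float, float] = (0.01, 0.05, 0.1)
) -> str:
    """Tier label for a (possibly adjusted) p-value."""
    t1, t2, t3 = thresholds
    if value < t1:
        return "p<%g" % t1
    if value < t2:
        return "p<%g" % t2
    if value < t3:
        return "p<%g" % t3
    return "ns"


def _align_pair(
    labeled: CountTable, control: CountTable, pools: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    for name, table in (("labeled", labeled), ("control", control)):
        missing = [p for p in pools if p not in table.samples]
        if missing:
            raise ValueError(f"{name} table lacks pooled fraction(s) {missing}")
    taxa = labeled.taxa.union(control.taxa)
    lab = labeled.counts.reindex(index=taxa, fill_value=0)
    ctl = control.counts.reindex(index=taxa, fill_value=0)
    # taxa absent from both tables carry no information
    keep = (lab.sum(axis=1) + ctl.sum(axis=1)) > 0
    lab, ctl = lab[keep], ctl[keep]
    lineages = labeled.lineages.combine_first(control.lineages).reindex(lab.index)
    return lab, ctl, lineages


def compute_activity(
    labeled: CountTable,
    control: CountTable,
    dense_pools: Sequence[str],
    tier_on: str = "q",
    fdr_within_pool: bool = True,
) -> pd.DataFrame:
    """Activity A, Fisher p and BH-FDR q per taxon per dense pooled fraction.

    Taxa present in only one table are zero-filled in the other; taxa
    absent from both are dropped.  ``tier_on`` selects whether the
    significance tier is read off the adjusted (``"q"``, default) or raw
    (``"p"``) value.  By default the BH adjustment is applied within
    each dense pooled fraction across taxa; ``fdr_within_pool=False``
    pools all tests instead.
    """
    if not dense_pools:
        raise ValueError("no dense pooled fractions given")
    if tier_on not in ("p", "q"):
        raise ValueError("tier_on must be 'p' or 'q'")
    lab, ctl, _ = _align_pair(labeled, control, dense_pools)
    ns_lab = lab.sum(axis=0)
    ns_ctl = ctl.sum(axis=0)
    rows = []
    for pool in dense_pools:
        if ns_lab[pool] <= 0 or ns_ctl[pool] <= 0:
            raise ValueError(f"pooled fraction {pool!r} has zero total sequences")
        for taxon in lab.index:
            t_lab = int(lab.at[taxon, pool])
            t_ctl = int(ctl.at[taxon, pool])
            a = 100.0 * t_lab / ns_lab[pool] - 100.0 * t_ctl / ns_ctl[pool]
            p = fisher_enrichment_p(t_lab, int(ns_lab[pool]), t_ctl, int(ns_ctl[pool]))
            rows.append(
                {
                    "taxon": taxon,
                    "pool": pool,
                    "A": a,
                    "tNS_labeled": t_lab,
                    "NS_labeled": int(ns_lab[pool]),
                    "tNS_control": t_ctl,
                    "NS_control": int(ns_ctl[pool]),
                    "p": p,
                }
            )
    records = pd.DataFrame(rows)
    if fdr_within_pool:
        records["q"] = records.groupby("pool")["p"].transform(lambda s: bh_fdr(s.values))
    else:
        records["q"] = bh_fdr(records["p"].values)
    records["tier"] = records[tier_on].map(significance_tier)
    return records


def collapse_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts of all taxa sharing a taxonomy value at ``rank``.

    Taxa unresolved at that rank are grouped as ``unclassified <nearest
    resolved parent>`` so column totals are preserved.  The operation is
    idempotent: collapsing an already-collapsed table is a no-op.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_i = RANKS.index(rank)
    names, lineage_out = [], {}
    for taxon, lin in table.lineages.items():
        parsed = parse_lineage(lin) if lin else {}
        if rank in parsed:
            name = parsed[rank]
        else:
            parent = next(
                (parsed[RANKS[j]] for j in range(rank_i - 1, -1, -1) if RANKS[j] in parsed),
                "root",
            )
            name = f"unclassified {parent}"
        names.append(name)
        kept = [f"{r[0]}__{parsed[r]}" for r in RANKS[: rank_i + 1] if r in parsed]
        lineage_out.setdefault(name, "; ".join(kept))
    collapsed = table.counts.groupby(pd.Index(names, name=table.counts.index.name)).sum()
    lineages = pd.Series({n: lineage_out[n] for n in collapsed.index}, name="taxonomy")
    return CountTable(collapsed, lineages, integral=table.integral)


def activity_heatmap_matrix(
    records: pd.DataFrame,
    annotation_symbols: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxa x dense-pool matrix of A values with significance annotations.

    Annotations follow the heatmap legend convention: ``**`` below 0.01,
    ``*`` below 0.05, ``+`` below 0.1, empty otherwise, read from the
    records' tier column.
    """
    if records.empty:
        raise ValueError("no activity records")
    if records.duplicated(subset=["taxon", "pool"]).any():
        raise ValueError("duplicate (taxon, pool) records")
    symbols = annotation_symbols or {"p<0.01": "**", "p<0.05": "*", "p<0.1": "+", "ns": ""}
    a = records.pivot(index="taxon", columns="pool", values="A")
    annot = (
        records.assign(sym=records["tier"].map(symbols))
        .pivot(index="taxon", columns="pool", values="sym")
        .fillna("")
    )
    return a, annot


def rank_by_activity(records: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Taxa ranked by their maximal activity over dense pooled fractions.

    Ties break lexicographically by taxon name.  This is the
    highest-activity-genera style of summary table.
    """
    if records.empty:
        raise ValueError("no activity records")
    best = (
        records.groupby("taxon")
        .agg(max_A=("A", "max"), min_q=("q", "min"))
        .sort_values(["max_A", "taxon"], ascending=[False, True])
        .reset_index()
    )
    return best.head(top_n) if top_n else best
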