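"""Rhizosphere community summaries.

Rank aggregation, relative abundance, top-k taxa pooling, alpha diversity
(Chao1 richness and Shannon entropy in natural-log units), and Bray-Curtis
dissimilarities suitable as input to the permutation Mantel test.

Alpha diversity is computed on raw counts; an optional seeded rarefaction
is available for users who want equal-depth comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy.spatial.distance import pdist, squareform

from .datamodel import TaxaTable
from .errors import DegenerateInputError, DomainError, ValidationError


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances at a given taxonomic rank."""

    proportions: pd.DataFrame
    rank: str = "taxon"

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy()
        if (arr < -1e-12).any():
            raise ValidationError("proportions must be >= 0")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each sample's proportions must sum to 1")


def aggregate_rank(table: TaxaTable, rank: str = "phylum") -> TaxaTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Taxa whose lineage lacks the rank are pooled into ``"Unclassified"``.
    Column sums (per-sample totals) are preserved exactly.
    """
    labels = []
    available: set[str] = set()
    for taxon in table.taxon_ids:
        ranks = table.lineage.get(taxon, {})
        available.update(ranks)
        labels.append(ranks.get(rank, "Unclassified"))
    if all(lab == "Unclassified" for lab in labels):
        raise DomainError(
            f"rank {rank!r} absent from every lineage; available ranks: "
            f"{sorted(available) or 'none'}"
        )
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank)).sum().T
    lineage = {lab: {rank: lab} for lab in grouped.columns if lab != "Unclassified"}
    return TaxaTable(counts=grouped, lineage=lineage)


def relative_abundance(table: TaxaTable, rank: str = "taxon") -> AbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise DomainError(f"zero-total sample(s): {list(zero.index)}")
    return AbundanceTable(proportions=table.counts.div(totals, axis=0), rank=rank)


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over taxa with count > 0."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DomainError("counts must be >= 0")
    total = c.sum()
    if total == 0:
        raise DegenerateInputError("all counts are zero")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    S_obs + F1^2 / (2 F2) when doubletons exist; the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DomainError("counts must be >= 0")
    if c.sum() == 0:
        raise DegenerateInputError("all counts are zero")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def alpha_diversity(
    table: TaxaTable, rarefy_to: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon indices.

    With ``rarefy_to`` set, each sample is first subsampled without
    replacement to that depth (seeded); samples shallower than the target
    are rejected.
    """
    counts = table.counts
    if rarefy_to is not None:
        rng = np.random.default_rng(seed)
        short = counts.sum(axis=1) < rarefy_to
        if short.any():
            raise DomainError(
                f"sample(s) shallower than rarefaction depth {rarefy_to}: "
                f"{list(counts.index[short])}"
            )
        rarefied = {}
        for sample, row in counts.iterrows():
            pool = np.repeat(np.arange(len(row)), row.to_numpy())
            picked = rng.choice(pool, size=rarefy_to, replace=False)
            rarefied[sample] = np.bincount(picked, minlength=len(row))
        counts = pd.DataFrame.from_dict(
            rarefied, orient="index", columns=counts.columns
        )
    return pd.DataFrame(
        {
            "sample": counts.index,
            "chao1": [chao1(row.to_numpy()) for _, row in counts.iterrows()],
            "shannon": [shannon(row.to_numpy()) for _, row in counts.iterrows()],
        }
    ).set_index("sample")


def bray_curtis(table: TaxaTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix between samples.

    d(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b); symmetric, zero
    diagonal, entries in [0, 1].
    """
    counts = table.counts
    if counts.shape[0] < 2:
        raise DomainError("need at least 2 samples")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise DomainError(
            f"zero-total sample(s): {list(counts.index[totals == 0])}"
        )
    dist = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dist, index=counts.index, columns=counts.index)


def top_k(table: AbundanceTable, k: int) -> AbundanceTable:
    """Keep the k taxa with the largest mean relative abundance.

    Remaining taxa are pooled into ``"Others"`` so per-sample sums stay 1;
    ties at rank k break lexicographically by taxon name. If k >= the taxon
    count the table is returned with an all-zero ``"Others"`` column.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    props = table.proportions
    means = props.mean(axis=0)
    # sort by descending mean, then name, so ties at the cut are lexicographic
    ranked = sorted(props.columns, key=lambda t: (-means[t], str(t)))
    keep = ranked[:k]
    rest = ranked[k:]
    out = props[keep].copy()
    out["Others"] = props[rest].sum(axis=1) if rest else 0.0
    return AbundanceTable(proportions=out, rank=table.rank)
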