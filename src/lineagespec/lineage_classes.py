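"""Lineage-maintained genes, transcript-fate classification, profile groups.

The core inference of the pipeline.  After the zygote (Zy24) divides into the
apical cell (AC, founding the embryo-proper lineage ACL) and basal cell (BC,
founding the suspensor lineage BCL), genes upregulated in the same lineage at
both the 1-cell stage (AC vs BC) and 32-cell stage (32E vs 32S) are
"lineage-maintained".  Each AC-vs-BC DEG is further assigned a transcript
fate describing the mechanism that generated the daughter-cell asymmetry:

* inherited_asymmetric — a zygote-deposited transcript partitioned unevenly
  at division and gone by the 32-cell stage (Zy24 high, both 32-cell samples
  negligible);
* de_novo — absent in the zygote, transcribed afresh in the favored daughter
  (Zy24 negligible, favored daughter high);
* selective_deletion — a zygote transcript retained in the favored daughter
  and degraded in the other (Zy24 high, favored daughter high, other
  negligible);
* unclassified otherwise.

"High" and "negligible" are FPKM cutoffs (defaults 5 and 1) applied to mean
expression profiles per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantify import ExpressionMatrix

__all__ = [
    "LineageGeneSets",
    "FateThresholds",
    "lineage_maintained",
    "classify_transcript_fate",
    "cluster_profiles",
]


@dataclass
class LineageGeneSets:
    acl_maintained: set[str]
    bcl_maintained: set[str]
    per_contrast: dict[str, tuple[set[str], set[str]]] = field(
        default_factory=dict
    )


@dataclass
class FateThresholds:
    """FPKM cutoffs for the fate rules (config-exposed, not hard-coded)."""

    high_fpkm: float = 5.0
    negligible_fpkm: float = 1.0


def lineage_maintained(
    deg_1cell: tuple[set[str], set[str]],
    deg_32cell: tuple[set[str], set[str]],
) -> LineageGeneSets:
    """Intersect the AC:BC and 32E:32S DEG sets.

    ACL-maintained = up(AC:BC) ∩ up(32E:32S);
    BCL-maintained = down(AC:BC) ∩ down(32E:32S).
    """
    up1, down1 = deg_1cell
    up2, down2 = deg_32cell
    for up, down, name in ((up1, down1, "1-cell"), (up2, down2, "32-cell")):
        both = up & down
        if both:
            raise ValueError(
                f"malformed DE calls: genes both up and down at {name} "
                f"stage: {sorted(both)[:5]}"
            )
    return LineageGeneSets(
        acl_maintained=up1 & up2,
        bcl_maintained=down1 & down2,
        per_contrast={"AC:BC": (up1, down1), "32E:32S": (up2, down2)},
    )


def classify_transcript_fate(
    em: ExpressionMatrix,
    deg_ac_bc: tuple[set[str], set[str]],
    thresholds: FateThresholds | None = None,
) -> pd.DataFrame:
    """Assign a fate mechanism to every AC-vs-BC DEG.

    Returns a DataFrame indexed by gene_id with columns ``mechanism`` (one of
    inherited_asymmetric / de_novo / selective_deletion / unclassified) and
    ``favored_lineage`` (ACL for genes up in AC, BCL for genes up in BC).
    """
    th = thresholds or FateThresholds()
    needed = ["Zy24", "AC", "BC", "32E", "32S"]
    means = em.group_means(needed)  # raises KeyError on missing cell type

    up, down = deg_ac_bc
    rows = []
    for gene_set, favored in ((up, "ACL"), (down, "BCL")):
        daughter, other = ("AC", "BC") if favored == "ACL" else ("BC", "AC")
        for g in sorted(gene_set):
            zy = means.at[g, "Zy24"]
            d = means.at[g, daughter]
            o = means.at[g, other]
            late = max(means.at[g, "32E"], means.at[g, "32S"])
            if zy >= th.high_fpkm and late < th.negligible_fpkm:
                mech = "inherited_asymmetric"
            elif zy < th.negligible_fpkm and d >= th.high_fpkm:
                mech = "de_novo"
            elif (
                zy >= th.high_fpkm
                and d >= th.high_fpkm
                and o < th.negligible_fpkm
            ):
                mech = "selective_deletion"
            else:
                mech = "unclassified"
            rows.append((g, mech, favored))
    out = pd.DataFrame(
        rows, columns=["gene_id", "mechanism", "favored_lineage"]
    )
    return out.set_index("gene_id")


def cluster_profiles(
    em: ExpressionMatrix,
    genes: list[str] | set[str],
    k: int,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Group genes by the shape of their mean expression profile.

    Per-gene mean-FPKM profiles across cell types are z-scored (so only the
    shape matters, not the level) and clustered by average linkage on
    Euclidean distance, cut at k groups.  Returns a DataFrame indexed by
    gene_id with a ``group`` column in 1..k plus the z-scored profile.
    """
    genes = sorted(genes)
    if not genes:
        raise ValueError("empty gene set")
    if not 1 <= k <= len(genes):
        raise ValueError(f"k must be in [1, {len(genes)}], got {k}")
    means = em.group_means(cell_types)
    prof = means.loc[genes].to_numpy(dtype=float)
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant profiles become all-zero z rows
    z = (prof - mu) / sd
    if len(genes) == 1 or k == len(genes):
        labels = np.arange(1, len(genes) + 1) if k == len(genes) else [1]
    else:
        link = hierarchy.linkage(pdist(z), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    out = pd.DataFrame(z, index=pd.Index(genes, name="gene_id"),
                       columns=means.columns)
    out.insert(0, "group", labels)
    return out
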