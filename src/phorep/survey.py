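"""Multi-genome phosphatase repertoire statistics.

A survey table holds, per genome, the phylum, genome length and gene counts
for the eight non-specific phosphatase families (alkaline: PhoA, PhoK, PhoD,
PhoX; acid: AcpA, PhoN, AphA, NSAPc). The summary reports, per family and
for the alkaline aggregate, the fraction of genomes with at least k genes,
per-Mb gene densities with the focal genome's percentile, the regression of
total gene count on genome size, and a Kruskal-Wallis test of phosphatase
abundance across genome-size quantile bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FAMILIES = ("PhoA", "PhoK", "AcpA", "PhoD", "PhoX", "PhoN", "AphA", "NSAPc")
ALKALINE_FAMILIES = ("PhoA", "PhoK", "PhoD", "PhoX")


def build_survey(
    annotations_per_genome: dict[str, list],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the survey table from per-genome family annotations.

    ``annotations_per_genome`` maps genome_id to a list of annotations (any
    object with a ``family`` attribute, or plain family-name strings);
    ``metadata`` needs columns genome_id, phylum, genome_length (bp) and may
    carry total_genes. Families without hits get count 0.
    """
    required = {"genome_id", "phylum", "genome_length"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if metadata["genome_id"].duplicated().any():
        dups = metadata.loc[metadata["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_id: {dups}")
    rows = []
    for _, meta in metadata.iterrows():
        gid = meta["genome_id"]
        counts = dict.fromkeys(FAMILIES, 0)
        for ann in annotations_per_genome.get(gid, []):
            family = ann if isinstance(ann, str) else ann.family
            if family not in counts:
                raise ValueError(f"unknown family {family!r} for genome {gid!r}")
            counts[family] += 1
        row = {"genome_id": gid, "phylum": meta["phylum"],
               "genome_length": int(meta["genome_length"]), **counts}
        if "total_genes" in metadata.columns:
            row["total_genes"] = int(meta["total_genes"])
        rows.append(row)
    columns = ["genome_id", "phylum", "genome_length", *FAMILIES]
    if rows and "total_genes" in rows[0]:
        columns.append("total_genes")
    return pd.DataFrame(rows, columns=columns)


def density(count: float, genome_length: float) -> float:
    """Genes per Mb."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return count / (genome_length / 1e6)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H statistic and chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie_term == 0:
        raise ValueError("all observations identical")
    h /= tie_term
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return float(h), p


@dataclass
class SurveySummary:
    fraction_at_least: dict[str, dict[int, float]]  # family/aggregate -> k -> fraction
    densities: pd.DataFrame                          # genome_id x family densities per Mb
    focal_percentiles: dict[str, float] | None       # fraction of genomes strictly denser
    regression: dict[str, float]                     # slope, intercept, r2 (count vs bp)
    kruskal: dict[str, float] | None                 # statistic, pvalue (None if undefined)


def summarize(
    table: pd.DataFrame,
    k_values: tuple[int, ...] = (1, 4, 5),
    n_size_bins: int = 5,
    focal_genome: str | None = None,
) -> SurveySummary:
    """Survey statistics over the genome collection.

    Fractions use the alkaline aggregate (PhoA+PhoK+PhoD+PhoX) plus each
    family; the regression is total gene count against genome size (bp),
    using the total_genes column when present and the summed phosphatase
    counts otherwise; Kruskal-Wallis compares total phosphatase counts
    across genome-size quantile bins (quintiles by default).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 genomes")
    t = table.copy()
    t["alkaline"] = t[list(ALKALINE_FAMILIES)].sum(axis=1)
    t["phosphatase_total"] = t[list(FAMILIES)].sum(axis=1)

    fraction_at_least: dict[str, dict[int, float]] = {}
    for name in ("alkaline", *FAMILIES):
        fraction_at_least[name] = {
            k: float((t[name] >= k).mean()) for k in sorted(k_values)
        }

    dens = pd.DataFrame({"genome_id": t["genome_id"]})
    for fam in (*FAMILIES, "alkaline"):
        dens[fam] = t[fam] / (t["genome_length"] / 1e6)

    focal_percentiles = None
    if focal_genome is not None:
        if focal_genome not in set(t["genome_id"]):
            raise KeyError(f"focal genome {focal_genome!r} not in table")
        focal_percentiles = {}
        for fam in (*FAMILIES, "alkaline"):
            focal = float(dens.loc[dens["genome_id"] == focal_genome, fam].iloc[0])
            focal_percentiles[fam] = float((dens[fam] > focal).mean())

    y = t["total_genes"] if "total_genes" in t.columns else t["phosphatase_total"]
    reg = stats.linregress(t["genome_length"], y)
    regression = {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r2": float(reg.rvalue ** 2),
    }

    kruskal = None
    try:
        bins = pd.qcut(t["genome_length"], q=n_size_bins, duplicates="drop")
    except ValueError:
        bins = None
    if bins is not None and bins.nunique() >= 2:
        groups = [
            t.loc[bins == cat, "phosphatase_total"].to_numpy()
            for cat in bins.cat.categories
        ]
        try:
            h, p = kruskal_wallis(groups)
            kruskal = {"statistic": h, "pvalue": p}
        except ValueError:
            kruskal = None
    return SurveySummary(fraction_at_least, dens, focal_percentiles, regression, kruskal)
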