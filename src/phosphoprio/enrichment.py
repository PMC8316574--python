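"""Enrichment statistics over regulated-site and regulated-gene sets.

Kinase-substrate and pathway enrichment use the one-sided hypergeometric
test with the enrichment ratio

    E-ratio = (m/M) / (n/N)

where N is the background size, n the background items annotated to the
unit (kinase or pathway), M the regulated items, and m the regulated items
annotated to the unit.  The p-value is the upper hypergeometric tail
P(X >= m).  A unit is flagged significant when p < alpha and E-ratio > 1;
no multiplicity correction is applied by default (a Benjamini-Hochberg
option is available for users who want one).

Score-set enrichment (e.g. tissue-expression scores per gene) uses a
two-tailed Z-test of a category's mean score against the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one unit (kinase or pathway)."""

    unit_id: str
    n_background: int  # N
    n_annotated: int  # n
    n_regulated: int  # M
    n_overlap: int  # m
    e_ratio: float
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha and self.e_ratio > 1.0


def hypergeom_enrichment(
    N: int, n: int, M: int, m: int, unit_id: str = ""
) -> EnrichmentResult:
    """E-ratio and one-sided hypergeometric tail for one unit.

    p = sum_{m'=m}^{min(n, M)} C(M, m') C(N-M, n-m') / C(N, n).
    The tail stops at min(n, M) since larger overlaps are impossible.
    Computed in log space by scipy for numerical stability at large N.
    """
    if not (0 <= m <= min(n, M) and n <= N and M <= N and M > 0 and n > 0):
        raise ValueError(
            f"invalid counts N={N}, n={n}, M={M}, m={m}"
        )
    e_ratio = (m / M) / (n / N)
    p = float(stats.hypergeom.sf(m - 1, N, M, n))
    return EnrichmentResult(
        unit_id=unit_id,
        n_background=N,
        n_annotated=n,
        n_regulated=M,
        n_overlap=m,
        e_ratio=e_ratio,
        p_value=min(p, 1.0),
    )


def _enrich_units(
    background: set[str],
    regulated: set[str],
    unit_members: Mapping[str, set[str]],
    alpha: float,
    adjust: bool,
) -> pd.DataFrame:
    missing = regulated - background
    if missing:
        raise ValueError(
            f"{len(missing)} regulated items absent from background, "
            f"e.g. {sorted(missing)[:3]}"
        )
    N, M = len(background), len(regulated)
    rows = []
    for unit_id in sorted(unit_members):
        members = unit_members[unit_id] & background
        n = len(members)
        if n == 0 or M == 0:
            continue
        m = len(members & regulated)
        res = hypergeom_enrichment(N, n, M, m, unit_id=unit_id)
        rows.append(
            {
                "unit_id": unit_id,
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "e_ratio": res.e_ratio,
                "p_value": res.p_value,
                "significant": res.significant(alpha),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["unit_id", "N", "n", "M", "m", "e_ratio", "p_value", "significant"],
    )
    if adjust and not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = (df["p_adjusted"] < alpha) & (df["e_ratio"] > 1.0)
    return df.sort_values(["p_value", "unit_id"]).reset_index(drop=True)


def enrich_kinases(
    all_sites: Iterable[str],
    regulated_sites: Mapping[str, Iterable[str]],
    kinase_edges: Iterable[tuple[str, str]],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Kinase-substrate enrichment per direction of regulation.

    ``regulated_sites`` maps direction label (e.g. "hyper"/"hypo") to site
    ids; the background is all identified phosphosites.  One test per
    kinase per direction; a kinase is flagged when p < alpha and
    E-ratio > 1 (raw p by default, matching the stated decision rule).
    """
    background = set(all_sites)
    members: dict[str, set[str]] = {}
    for family, site_id in kinase_edges:
        members.setdefault(family, set()).add(site_id)
    frames = []
    for direction, sites in regulated_sites.items():
        df = _enrich_units(background, set(sites), members, alpha, adjust)
        df.insert(0, "direction", direction)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def enrich_pathways(
    background_genes: Iterable[str],
    regulated_genes: Iterable[str],
    gene_pathways: Mapping[str, Iterable[str]] | pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pathway enrichment of regulated genes against a gene background.

    ``gene_pathways`` maps gene -> pathway ids (or a two-column frame
    gene/pathway).  Same statistic and decision rule as kinase enrichment,
    with genes as items.
    """
    if isinstance(gene_pathways, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for gene, pathway in gene_pathways.itertuples(index=False):
            mapping.setdefault(str(gene), set()).add(str(pathway))
        gene_pathways = mapping
    members: dict[str, set[str]] = {}
    for gene, pathways in gene_pathways.items():
        for p in pathways:
            members.setdefault(p, set()).add(gene)
    return _enrich_units(
        set(background_genes), set(regulated_genes), members, alpha, adjust
    )


def score_set_ztest(
    item_scores: Iterable[float],
    population_mean: float,
    population_sd: float,
) -> tuple[float, float]:
    """Two-tailed Z-test of a category's mean score against the population.

    Z = (mean_items - mean_pop) / (sd_pop / sqrt(n_items));
    p = 2 (1 - Phi(|Z|)).  The population parameters are those of all
    scored items (members included).
    """
    values = np.asarray(list(item_scores), dtype=float)
    if values.size < 1:
        raise ValueError("need at least one item score")
    if population_sd <= 0:
        raise ValueError("population sd must be positive")
    z = (values.mean() - population_mean) / (population_sd / np.sqrt(values.size))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
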