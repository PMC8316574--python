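"""Encoding of the six per-site features used by the functional-site model.

Each phosphosite is encoded into eight numeric columns:

==============  =================================================
column          meaning
==============  =================================================
ukf_count       number of distinct upstream kinase families with a
                predicted edge to the site
rcs             residue conservation score (see ``conservation``)
idm_count       number of interaction partners (domains/motifs) of
                the domains containing the site; 0 outside domains
asc             1 if an acetylation site lies within +/-15 residues
                on the same protein, else 0
rsa             predicted relative surface accessibility, in [0,1]
ss_helix,
ss_strand,
ss_coil         predicted secondary-structure probabilities
==============  =================================================

No scaling or standardization is applied before regression, so learned
coefficients are directly comparable across runs on the raw encodings.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .core_io import AnnotationBundle, PhosphositeRecord

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "ukf_count",
    "rcs",
    "idm_count",
    "asc",
    "rsa",
    "ss_helix",
    "ss_strand",
    "ss_coil",
]

ACETYL_WINDOW = 15  # residues, inclusive on both flanks


def count_upstream_kinase_families(
    kinase_edges: Iterable[tuple[str, str]], site_id: str
) -> int:
    """Distinct kinase families with a predicted edge to the site (set semantics)."""
    return len({family for family, sid in kinase_edges if sid == site_id})


def count_interacting_domains_motifs(
    domain_spans: Iterable[tuple[str, int, int, str]],
    domain_partner_counts: Mapping[str, int],
    site: PhosphositeRecord,
    overlap_policy: Literal["sum", "max"] = "sum",
) -> int:
    """Interaction-partner count of the domains containing the site.

    A site outside every domain scores 0.  When overlapping domains contain
    the site, their partner counts are summed by default (``max`` available
    for users who prefer the most-connected domain alone).
    """
    counts = [
        domain_partner_counts.get(domain_id, 0)
        for acc, start, end, domain_id in domain_spans
        if acc == site.accession and start <= site.position <= end
    ]
    if not counts:
        return 0
    return sum(counts) if overlap_policy == "sum" else max(counts)


def acetylation_cooccurrence_flag(
    acetyl_sites: Iterable[tuple[str, int]],
    site: PhosphositeRecord,
    window: int = ACETYL_WINDOW,
) -> int:
    """1 iff an acetylation site on the same protein lies within ``window`` residues."""
    for acc, pos in acetyl_sites:
        if acc == site.accession and abs(pos - site.position) <= window:
            return 1
    return 0


class MissingFeatureError(KeyError):
    """A site lacks a required annotation under the ``error`` policy."""


def assemble_feature_table(
    sites: Sequence[PhosphositeRecord],
    bundle: AnnotationBundle,
    conservation_scores: Mapping[str, float],
    missing_policy: Literal["error", "impute-zero"] = "impute-zero",
    overlap_policy: Literal["sum", "max"] = "sum",
) -> pd.DataFrame:
    """Build the per-site feature table (one row per site, 8 columns).

    ``conservation_scores`` maps site_id -> RCS.  Count-type features (ukf,
    idm, asc) default to 0 when no annotation mentions the site — absence of
    an edge is a genuine zero.  Value-type features (rcs, rsa, ss) are
    subject to ``missing_policy``: ``impute-zero`` fills 0 (ss uniformly as
    coil) with a logged count, ``error`` raises naming the first site.
    """
    rows = []
    n_imputed = 0
    for site in sites:
        sid = site.site_id
        row: dict[str, float] = {
            "site_id": sid,
            "ukf_count": count_upstream_kinase_families(bundle.kinase_edges, sid),
            "idm_count": count_interacting_domains_motifs(
                bundle.domain_spans, bundle.domain_partner_counts, site, overlap_policy
            ),
            "asc": acetylation_cooccurrence_flag(bundle.acetyl_sites, site),
        }
        missing = []
        if sid in conservation_scores:
            row["rcs"] = float(conservation_scores[sid])
        else:
            missing.append("rcs")
            row["rcs"] = 0.0
        if sid in bundle.rsa:
            row["rsa"] = float(bundle.rsa[sid])
        else:
            missing.append("rsa")
            row["rsa"] = 0.0
        if sid in bundle.ss_probs:
            row["ss_helix"], row["ss_strand"], row["ss_coil"] = bundle.ss_probs[sid]
        else:
            missing.append("ss")
            row["ss_helix"], row["ss_strand"], row["ss_coil"] = 0.0, 0.0, 1.0
        if missing:
            if missing_policy == "error":
                raise MissingFeatureError(
                    f"site {sid} missing annotations: {', '.join(missing)}"
                )
            n_imputed += len(missing)
        rows.append(row)
    if n_imputed:
        logger.info("imputed %d missing feature values across %d sites",
                    n_imputed, len(rows))
    df = pd.DataFrame(rows, columns=["site_id", *FEATURE_COLUMNS])
    return df.set_index("site_id")
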