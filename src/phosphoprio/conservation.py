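"""Residue conservation scoring of phosphosites on a species phylogeny.

For a phosphosite with orthologs aligned in a multiple sequence alignment,
the residue conservation score is

    RCS = MBL * RCR = MBL * Np / N

where MBL (maximum branch length) is the longest patristic distance between
any two species carrying a conserved phosphoacceptor at the aligned column,
Np is the number of such species within the smallest clade spanning them,
and N is the number of analysis species (species with an ortholog in the
alignment) within that clade.  A site conserved only in the reference
species has MBL = 0 and therefore RCS = 0.

By default serine and threonine form one phosphoacceptor class (S/T kinases
act on either) while tyrosine is its own class; ``strict_residue=True``
requires the exact residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .core_io import PhosphositeRecord, PhyloTree, ValidationError, read_fasta


@dataclass
class OrthologAlignment:
    """One protein's ortholog MSA: species -> aligned row (gaps '-')."""

    rows: dict[str, str]
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.rows:
            raise ValidationError(
                f"reference species {self.reference_species!r} absent from alignment"
            )
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(f"alignment rows have unequal lengths {lengths}")

    @property
    def species(self) -> set[str]:
        return set(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_species]

    @property
    def ungapped_reference(self) -> str:
        return self.reference_row.replace("-", "")


@dataclass(frozen=True)
class ConservationScore:
    """RCS decomposition for one site."""

    mbl: float
    np_conserved: int
    n_clade: int
    mbl_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def rcr(self) -> float:
        return self.np_conserved / self.n_clade

    @property
    def rcs(self) -> float:
        return self.mbl * self.rcr


def read_alignment_fasta(path: str | Path, reference_species: str) -> OrthologAlignment:
    """Read an aligned FASTA where record ids are species labels."""
    records = read_fasta(path)
    return OrthologAlignment(
        rows={r.accession: r.sequence for r in records},
        reference_species=reference_species,
    )


def map_site_to_column(msa: OrthologAlignment, position: int) -> int:
    """0-based alignment column holding the reference residue at 1-based ``position``.

    Gaps in the reference row are skipped while counting residues.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    seen = 0
    for col, char in enumerate(msa.reference_row):
        if char != "-":
            seen += 1
            if seen == position:
                return col
    raise ValueError(
        f"position {position} beyond ungapped reference length {seen}"
    )


def _phospho_equivalent(residue: str, site_residue: str, strict: bool) -> bool:
    if strict:
        return residue == site_residue
    if site_residue in "ST":
        return residue in "ST"
    return residue == site_residue  # Y matches only Y


def conserved_species(
    msa: OrthologAlignment,
    column: int,
    site_residue: str,
    strict_residue: bool = False,
) -> set[str]:
    """Species whose residue at ``column`` is phosphoacceptor-equivalent.

    The reference species is always included.
    """
    conserved = {msa.reference_species}
    for species, row in msa.rows.items():
        if _phospho_equivalent(row[column], site_residue, strict_residue):
            conserved.add(species)
    return conserved


def max_branch_length(
    tree: PhyloTree, species: set[str]
) -> tuple[float, list[tuple[str, str]]]:
    """Longest patristic distance over unordered pairs within ``species``.

    Returns (MBL, all tied endpoint pairs).  A singleton (or empty) set has
    MBL 0 and no pairs.
    """
    labels = sorted(species)
    for label in labels:
        if label not in tree.leaf_labels:
            raise KeyError(f"species {label!r} not on tree")
    if len(labels) < 2:
        return 0.0, []
    best = 0.0
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = tree.distance(a, b)
            if d > best + 1e-12:
                best, pairs = d, [(a, b)]
            elif abs(d - best) <= 1e-12:
                pairs.append((a, b))
    return best, pairs


def residue_conservation_score(
    msa: OrthologAlignment,
    tree: PhyloTree,
    site: PhosphositeRecord,
    strict_residue: bool = False,
) -> ConservationScore:
    """Compute RCS = MBL * Np / N for one site.

    N counts the analysis species — those with a row in the alignment —
    inside the smallest clade (MRCA subtree) spanning the conserved set;
    species lacking an ortholog contribute to neither Np nor N.
    """
    column = map_site_to_column(msa, site.position)
    ref_char = msa.reference_row[column]
    if ref_char != site.residue:
        raise ValidationError(
            f"{site.site_id}: alignment column {column} holds {ref_char!r}, "
            f"expected {site.residue!r}"
        )
    conserved = conserved_species(msa, column, site.residue, strict_residue)
    mbl, pairs = max_branch_length(tree, conserved)
    if len(conserved) < 2:
        return ConservationScore(mbl=0.0, np_conserved=1, n_clade=1)
    clade = tree.clade_leaves(conserved)
    analysis = clade & msa.species
    return ConservationScore(
        mbl=mbl,
        np_conserved=len(conserved),
        n_clade=len(analysis),
        mbl_pairs=tuple(pairs),
    )
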