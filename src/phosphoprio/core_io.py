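"""Domain types, file formats, and validation shared by every stage.

The package works on four kinds of input, all plain text:

* **site tables** — tab-delimited with one phosphosite per row
  (accession, full protein sequence, 1-based position, residue);
* **quantitation tables** — long-format TSV of per-replicate light/heavy
  isotope ratios keyed by phosphoisoform and genotype;
* **annotation tables** — precomputed per-site predictor outputs
  (kinase-site edges, acetylation sites, domain spans and partner counts,
  surface accessibility, secondary-structure probabilities);
* **sequences and trees** — FASTA (proteins, ortholog alignments) and
  Newick (species phylogeny with branch lengths).

Coordinates are 1-based and inclusive throughout, matching the residue
numbering used on protein records (e.g. "T492"); conversion to 0-based
indices happens only at array boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PHOSPHO_RESIDUES = frozenset("STY")
#: 20 standard amino acids plus X for unknown residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ValidationError(ValueError):
    """Raised when an input record violates a declared invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhosphositeRecord:
    """A single phosphosite anchored to a protein sequence.

    Attributes
    ----------
    accession : str
        Protein identifier (treated as an opaque string).
    position : int
        1-based residue index within the protein sequence.
    residue : str
        The phosphoacceptor residue, one of S, T, Y.
    """

    accession: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValidationError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )

    @property
    def site_id(self) -> str:
        """Stable key of the form ``accession:residue+position``, e.g. ``P1:S5``."""
        return f"{self.accession}:{self.residue}{self.position}"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.accession}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}"
            )


@dataclass
class IsoformQuant:
    """Per-genotype replicate ratios of one phosphoisoform.

    A phosphoisoform is a peptide-derived record of one or more co-occurring
    phosphosites on one protein; its ``isoform_id`` has the form
    ``ACC:S5`` (single site) or ``ACC:S5+T9`` (multi-site).
    ``ratios`` maps genotype label -> list of normalized light/heavy ratio
    measurements, one per technical replicate with a confident quantitation.
    """

    isoform_id: str
    ratios: dict[str, list[float]]

    def __post_init__(self) -> None:
        for genotype, values in self.ratios.items():
            for v in values:
                if not v > 0:
                    raise ValidationError(
                        f"{self.isoform_id}/{genotype}: ratio must be > 0, got {v}"
                    )

    @property
    def accession(self) -> str:
        return self.isoform_id.split(":", 1)[0]

    @property
    def site_ids(self) -> list[str]:
        """Site ids carried by this isoform, e.g. ``A:S5+T9`` -> [A:S5, A:T9]."""
        acc, sites = self.isoform_id.split(":", 1)
        return [f"{acc}:{s}" for s in sites.split("+")]

    def n_measurements(self, genotype: str) -> int:
        return len(self.ratios.get(genotype, []))


@dataclass
class AnnotationBundle:
    """Per-site predictor outputs consumed as flat tables.

    Stands in for upstream kinase-substrate prediction, acetylation-site
    prediction, domain detection with interaction-partner counts, and
    surface-accessibility / secondary-structure prediction.
    """

    kinase_edges: set[tuple[str, str]] = field(default_factory=set)
    acetyl_sites: set[tuple[str, int]] = field(default_factory=set)
    domain_spans: list[tuple[str, int, int, str]] = field(default_factory=list)
    domain_partner_counts: dict[str, int] = field(default_factory=dict)
    rsa: dict[str, float] = field(default_factory=dict)
    ss_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Outcome of annotation validation: one message per offending row."""

    problems: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def ok(self) -> bool:
        return not self.problems


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted species tree with branch lengths, wrapping dendropy.

    Provides leaf-to-leaf path distances and smallest-spanning-clade
    queries needed by the conservation score.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge may be lengthless
            if edge.length is None:
                raise ValidationError("tree edge without branch length")
            if edge.length < 0:
                raise ValidationError("negative branch length")
        self._leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        pdm = tree.phylogenetic_distance_matrix()
        self._dist: dict[tuple[str, str], float] = {}
        for t1 in tree.taxon_namespace:
            for t2 in tree.taxon_namespace:
                self._dist[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)

    @property
    def leaf_labels(self) -> set[str]:
        return set(self._leaves)

    def distance(self, a: str, b: str) -> float:
        """Patristic (sum-of-branch-lengths) distance between two leaves."""
        for label in (a, b):
            if label not in self._leaves:
                raise KeyError(f"species {label!r} not on tree")
        return self._dist[(a, b)]

    def clade_leaves(self, species: Iterable[str]) -> set[str]:
        """Leaf set of the smallest clade (MRCA subtree) spanning ``species``."""
        species = list(species)
        for label in species:
            if label not in self._leaves:
                raise KeyError(f"species {label!r} not on tree")
        if len(species) == 1:
            return {species[0]}
        mrca = self._tree.mrca(taxon_labels=species)
        return {leaf.taxon.label for leaf in mrca.leaf_iter()}


def read_newick(path: str | Path) -> PhyloTree:
    """Read a single rooted Newick tree with branch lengths on all edges."""
    text = Path(path).read_text()
    trees = dendropy.TreeList.get(
        data=text, schema="newick", preserve_underscores=True
    )
    if len(trees) == 0:
        raise ValidationError(f"no tree found in {path}")
    if len(trees) > 1:
        raise ValidationError(f"expected a single tree in {path}, found {len(trees)}")
    return PhyloTree(trees[0])


# ---------------------------------------------------------------------------
# Sequence and table readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA; accession = header token before whitespace.

    Sequences are uppercased on read. Order is preserved.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise ValidationError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(ProteinRecord(accession=accession, sequence=str(rec.seq).upper()))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records],
        str(path),
        "fasta",
    )


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV table: tab separator, '#' comment lines, required header row."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_site_table(
    path: str | Path,
) -> tuple[list[PhosphositeRecord], list[ProteinRecord]]:
    """Read a tab-delimited phosphosite table.

    Expected columns: ``accession``, ``sequence`` (full protein sequence),
    ``position`` (1-based), ``residue`` (S/T/Y).  Each record is validated
    against its sequence; sequences are deduplicated by accession and must
    agree between rows sharing an accession.
    """
    df = read_tsv(path, dtype={"accession": str, "sequence": str, "residue": str})
    required = ["accession", "sequence", "position", "residue"]
    if list(df.columns[:4]) != required:
        raise ValidationError(
            f"site table must have columns {required}, got {list(df.columns)}"
        )
    sites: list[PhosphositeRecord] = []
    sequences: dict[str, str] = {}
    seen_ids: set[str] = set()
    for row in df.itertuples(index=False):
        seq = row.sequence.upper()
        prior = sequences.get(row.accession)
        if prior is not None and prior != seq:
            raise ValidationError(
                f"accession {row.accession} carries conflicting sequences"
            )
        sequences[row.accession] = seq
        rec = PhosphositeRecord(
            accession=row.accession, position=int(row.position), residue=row.residue
        )
        if rec.position > len(seq):
            raise ValidationError(
                f"{rec.site_id}: position beyond sequence length {len(seq)}"
            )
        actual = seq[rec.position - 1]
        if actual != rec.residue:
            raise ValidationError(
                f"{rec.site_id}: sequence has {actual!r} at position "
                f"{rec.position}, declared {rec.residue!r}"
            )
        if rec.site_id in seen_ids:
            raise ValidationError(f"duplicate site {rec.site_id}")
        seen_ids.add(rec.site_id)
        sites.append(rec)
    proteins = [ProteinRecord(a, s) for a, s in sequences.items()]
    return sites, proteins


def write_site_table(
    sites: Sequence[PhosphositeRecord],
    proteins: Mapping[str, str] | Sequence[ProteinRecord],
    path: str | Path,
) -> None:
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p.sequence for p in proteins}
    df = pd.DataFrame(
        {
            "accession": [s.accession for s in sites],
            "sequence": [proteins[s.accession] for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
        }
    )
    write_tsv(df, path)


def read_quant_table(path: str | Path) -> list[IsoformQuant]:
    """Read a long-format quantitation TSV (isoform_id, genotype, replicate, ratio)."""
    df = read_tsv(path, dtype={"isoform_id": str, "genotype": str})
    required = {"isoform_id", "genotype", "replicate", "ratio"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"quant table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    isoforms = []
    for isoform_id, grp in df.groupby("isoform_id", sort=True):
        ratios = {
            genotype: [float(v) for v in sub.sort_values("replicate")["ratio"]]
            for genotype, sub in grp.groupby("genotype", sort=True)
        }
        isoforms.append(IsoformQuant(isoform_id=str(isoform_id), ratios=ratios))
    return isoforms


def write_quant_table(isoforms: Sequence[IsoformQuant], path: str | Path) -> None:
    rows = []
    for iso in isoforms:
        for genotype in sorted(iso.ratios):
            for rep, ratio in enumerate(iso.ratios[genotype], start=1):
                rows.append((iso.isoform_id, genotype, rep, ratio))
    write_tsv(
        pd.DataFrame(rows, columns=["isoform_id", "genotype", "replicate", "ratio"]),
        path,
    )


# ---------------------------------------------------------------------------
# Annotation bundle I/O and validation
# ---------------------------------------------------------------------------

_ANNOTATION_FILES = {
    "kinase_edges": ["kinase_family", "site_id"],
    "acetyl": ["accession", "position"],
    "domains": ["accession", "start", "end", "domain_id"],
    "partners": ["domain_id", "n_partners"],
    "rsa": ["site_id", "rsa"],
    "ss": ["site_id", "p_helix", "p_strand", "p_coil"],
}


def read_annotations(directory: str | Path) -> AnnotationBundle:
    """Read an annotation bundle from a directory of TSVs.

    Expected files: ``kinase_edges.tsv``, ``acetyl.tsv``, ``domains.tsv``,
    ``partners.tsv``, ``rsa.tsv``, ``ss.tsv``.  Missing files yield empty
    components (every feature then encodes to its no-annotation value).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"annotation directory {directory} does not exist")
    bundle = AnnotationBundle()
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in _ANNOTATION_FILES.items():
        f = directory / f"{name}.tsv"
        if f.exists():
            df = read_tsv(f)
            missing = set(columns) - set(df.columns)
            if missing:
                raise ValidationError(f"{f}: missing columns {sorted(missing)}")
            tables[name] = df
    if "kinase_edges" in tables:
        t = tables["kinase_edges"]
        bundle.kinase_edges = set(zip(t.kinase_family.astype(str), t.site_id.astype(str)))
    if "acetyl" in tables:
        t = tables["acetyl"]
        bundle.acetyl_sites = set(zip(t.accession.astype(str), t.position.astype(int)))
    if "domains" in tables:
        t = tables["domains"]
        bundle.domain_spans = [
            (str(r.accession), int(r.start), int(r.end), str(r.domain_id))
            for r in t.itertuples(index=False)
        ]
    if "partners" in tables:
        t = tables["partners"]
        bundle.domain_partner_counts = dict(
            zip(t.domain_id.astype(str), t.n_partners.astype(int))
        )
    if "rsa" in tables:
        t = tables["rsa"]
        bundle.rsa = dict(zip(t.site_id.astype(str), t.rsa.astype(float)))
    if "ss" in tables:
        t = tables["ss"]
        bundle.ss_probs = {
            str(r.site_id): (float(r.p_helix), float(r.p_strand), float(r.p_coil))
            for r in t.itertuples(index=False)
        }
    return bundle


def write_annotations(bundle: AnnotationBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tsv(
        pd.DataFrame(
            sorted(bundle.kinase_edges), columns=["kinase_family", "site_id"]
        ),
        directory / "kinase_edges.tsv",
    )
    write_tsv(
        pd.DataFrame(sorted(bundle.acetyl_sites), columns=["accession", "position"]),
        directory / "acetyl.tsv",
    )
    write_tsv(
        pd.DataFrame(
            bundle.domain_spans, columns=["accession", "start", "end", "domain_id"]
        ),
        directory / "domains.tsv",
    )
    write_tsv(
        pd.DataFrame(
            sorted(bundle.domain_partner_counts.items()),
            columns=["domain_id", "n_partners"],
        ),
        directory / "partners.tsv",
    )
    write_tsv(
        pd.DataFrame(sorted(bundle.rsa.items()), columns=["site_id", "rsa"]),
        directory / "rsa.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [(sid, *probs) for sid, probs in sorted(bundle.ss_probs.items())],
            columns=["site_id", "p_helix", "p_strand", "p_coil"],
        ),
        directory / "ss.tsv",
    )


SS_SUM_TOLERANCE = 0.01


def validate_annotations(
    bundle: AnnotationBundle,
    proteins: Mapping[str, str] | Sequence[ProteinRecord],
    strict: bool = True,
) -> ValidationReport:
    """Validate an annotation bundle against protein sequences.

    Checks out-of-range positions, unknown accessions, RSA range, and
    secondary-structure triples whose entries are negative or do not sum to
    1 within ``SS_SUM_TOLERANCE``.  In strict mode (default) any problem
    raises; in lenient mode offending rows are dropped from the bundle and
    counted in the report.  Strict is the default because silently dropping
    rows corrupts enrichment backgrounds.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p.sequence for p in proteins}
    report = ValidationReport()

    bad_acetyl = set()
    for acc, pos in bundle.acetyl_sites:
        if acc not in proteins:
            report.problems.append(f"acetyl: unknown accession {acc}")
            bad_acetyl.add((acc, pos))
        elif not 1 <= pos <= len(proteins[acc]):
            report.problems.append(f"acetyl: {acc} position {pos} out of range")
            bad_acetyl.add((acc, pos))

    bad_domains = []
    for span in bundle.domain_spans:
        acc, start, end, domain_id = span
        if acc not in proteins:
            report.problems.append(f"domains: unknown accession {acc}")
            bad_domains.append(span)
        elif not 1 <= start <= end <= len(proteins[acc]):
            report.problems.append(
                f"domains: {acc} span {start}-{end} invalid for length "
                f"{len(proteins[acc])}"
            )
            bad_domains.append(span)

    bad_rsa = []
    for site_id, value in bundle.rsa.items():
        if not 0.0 <= value <= 1.0:
            report.problems.append(f"rsa: {site_id} value {value} outside [0,1]")
            bad_rsa.append(site_id)

    bad_ss = []
    for site_id, probs in bundle.ss_probs.items():
        if min(probs) < 0 or abs(sum(probs) - 1.0) > SS_SUM_TOLERANCE:
            report.problems.append(
                f"ss: {site_id} probabilities {probs} invalid "
                f"(negative entry or sum != 1)"
            )
            bad_ss.append(site_id)

    if report.problems and strict:
        raise ValidationError(
            f"{len(report.problems)} annotation problems; first: {report.problems[0]}"
        )
    if report.problems:
        bundle.acetyl_sites -= bad_acetyl
        for span in bad_domains:
            bundle.domain_spans.remove(span)
        for site_id in bad_rsa:
            del bundle.rsa[site_id]
        for site_id in bad_ss:
            del bundle.ss_probs[site_id]
        report.n_dropped = (
            len(bad_acetyl) + len(bad_domains) + len(bad_rsa) + len(bad_ss)
        )
        logger.warning("dropped %d invalid annotation rows", report.n_dropped)
    return report
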